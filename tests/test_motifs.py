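"""PWM thresholds, scanning, motif classes, and positional analyses."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cobind.motifs import (
    SCORE_STEP,
    MotifClass,
    MotifHit,
    PeakMotifProfile,
    PositionWeightMatrix,
    best_window_score,
    classify_peak,
    composite_spacing,
    has_tead_motif,
    positional_histogram,
    scan_sequence,
    score_distribution,
    score_threshold_from_pvalue,
)
from cobind.motifs import _integer_scores
from cobind.simulate import _consensus_pwm


def enumeration_threshold(pwm, p, step=SCORE_STEP):
    """Independent oracle: exhaustive enumeration of all 4^W windows on the
    shared score discretization."""
    ints = _integer_scores(pwm, step).astype(float)
    W = pwm.width
    total = np.zeros(1)
    for j in range(W):
        total = (total[:, None] + ints[j][None, :]).ravel()
    bg = pwm.background
    weights = np.ones(1)
    for j in range(W):
        weights = (weights[:, None] * bg[None, :]).ravel()
    # aggregate windows sharing a discretized score before computing tails
    uniq, inv = np.unique(total, return_inverse=True)
    mass = np.bincount(inv, weights=weights)
    tail = np.cumsum(mass[::-1])[::-1]
    ok = np.flatnonzero(tail <= p)
    if len(ok) == 0:
        return float(uniq[-1] * step + step)
    return float(uniq[ok[0]] * step)


def random_pwm(rng, width, pseudocount=1e-3, uniform_bg=True):
    probs = rng.dirichlet(np.ones(4), size=width)
    bg = np.full(4, 0.25) if uniform_bg else rng.dirichlet(np.ones(4) * 10)
    return PositionWeightMatrix(f"rnd{width}", probs, bg, pseudocount)


class TestScoreThreshold:
    def test_width1_hand_example(self):
        pwm = PositionWeightMatrix("w1", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
        assert score_threshold_from_pvalue(pwm, 0.25) == pytest.approx(2.0, abs=2e-3)

    def test_near_one_pvalue_reaches_bottom_of_support(self, rng):
        # as p -> 1 the threshold descends to the bottom of the score
        # support (the exact minimum has tail probability 1, which can never
        # satisfy tail <= p for p < 1)
        pwm = random_pwm(rng, 4)
        thr = score_threshold_from_pvalue(pwm, 1 - 1e-12)
        grid, _, _ = score_distribution(pwm)
        assert thr <= grid[1] + 1e-12

    def test_width3_best_sequence_threshold(self, rng):
        pwm = random_pwm(rng, 3)
        # at p = 1/64 under uniform background only the best window passes
        thr = score_threshold_from_pvalue(pwm, 1 / 64)
        assert thr == pytest.approx(enumeration_threshold(pwm, 1 / 64), abs=1e-12)

    @pytest.mark.parametrize("width", [1, 2, 4, 6, 8])
    @pytest.mark.parametrize("p", [1e-2, 1e-3, 1e-4])
    def test_dp_matches_enumeration(self, width, p):
        rng = np.random.default_rng(width * 1000 + int(-np.log10(p)))
        for uniform_bg in (True, False):
            pwm = random_pwm(rng, width, uniform_bg=uniform_bg)
            assert score_threshold_from_pvalue(pwm, p) == pytest.approx(
                enumeration_threshold(pwm, p), abs=1e-12
            )

    def test_degenerate_row_errors(self):
        probs = np.array([[1.0, 0, 0, 0]])
        pwm = PositionWeightMatrix("deg", probs, np.array([0.0, 1 / 3, 1 / 3, 1 / 3]),
                                   pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            score_threshold_from_pvalue(pwm, 0.5)

    def test_invalid_pvalue_rejected(self, rng):
        pwm = random_pwm(rng, 3)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                score_threshold_from_pvalue(pwm, bad)


class TestScan:
    def test_perfect_match_hit(self):
        pwm = _consensus_pwm("ap1core", "TTGACTCAT", 0.97)
        hits = scan_sequence(pwm, "TTGACTCAT", threshold=10.0)
        assert [h for h in hits if h.strand == "+"][0].position == 0
        best = best_window_score(pwm, "TTGACTCAT")
        assert best == pytest.approx(pwm.max_score())

    def test_reverse_complement_reported_on_minus(self):
        pwm = _consensus_pwm("m", "TTGACTCAT", 0.97)
        rc = "ATGAGTCAA"
        hits = scan_sequence(pwm, rc, threshold=10.0)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].position == 0

    def test_strand_symmetry_property(self, rng):
        pwm = random_pwm(rng, 6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        thr = score_threshold_from_pvalue(pwm, 0.01)
        fwd = scan_sequence(pwm, seq, thr)
        rev = scan_sequence(pwm, rc, thr)
        L, W = len(seq), pwm.width
        mirrored = sorted(
            (L - W - h.position, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rev
        )
        original = sorted((h.position, h.strand, round(h.score, 9)) for h in fwd)
        assert mirrored == original

    def test_short_sequence_returns_empty(self, rng):
        pwm = random_pwm(rng, 8)
        assert scan_sequence(pwm, "ACGT", threshold=-100) == []

    def test_n_windows_skipped(self):
        pwm = _consensus_pwm("m", "ACGT", 0.97)
        hits = scan_sequence(pwm, "ACNGT", threshold=-1000)
        assert all("N" not in "ACNGT"[h.position : h.position + 4] for h in hits)

    def test_hit_rate_calibrated(self, rng):
        pwm = _consensus_pwm("cal", "ATTGACTCATCCG", 0.96)
        thr = score_threshold_from_pvalue(pwm, 1e-4)
        n_windows = 200_000
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n_windows + pwm.width - 1))
        hits = scan_sequence(pwm, seq, thr, both_strands=False, with_pvalues=False)
        rate = len(hits) / n_windows
        se = np.sqrt(1e-4 * (1 - 1e-4) / n_windows)
        assert rate <= 1e-4 + 3 * se


def _profile(**hits_per_motif):
    hits = {
        m: [MotifHit(position=p, strand="+", score=10.0, pvalue=1e-5) for p in pos]
        for m, pos in hits_per_motif.items()
    }
    return PeakMotifProfile(peak_id="pk", hits=hits, window_start=0, summit=150)


class TestClassification:
    def test_tead_monomer_or_dimer_rule(self):
        assert has_tead_motif(_profile(TEAD_dimer=[5]))
        assert has_tead_motif(_profile(TEAD_monomer=[5]))
        assert not has_tead_motif(_profile(AP1=[5]))

    @pytest.mark.parametrize(
        "hits,expected",
        [
            (dict(AP1=[1]), MotifClass.AP1_ONLY),
            (dict(AP1=[1], TEAD_monomer=[40]), MotifClass.AP1_TEAD),
            (dict(AP1=[1], TEAD_dimer=[40]), MotifClass.AP1_TEAD),
            (dict(STAT3=[1]), MotifClass.STAT3_ONLY),
            (dict(AP1=[1], TEAD_monomer=[40], STAT3=[80]), MotifClass.AP1_TEAD_STAT3),
            (dict(), MotifClass.NONE),
        ],
    )
    def test_class_labels(self, hits, expected):
        assert classify_peak(_profile(**hits)) == expected

    def test_monotone_adding_hits_never_removes_motifs(self, rng):
        motifs = ["AP1", "TEAD_monomer", "TEAD_dimer", "STAT3"]
        def label_set(label):
            return {
                m for m, flag in zip(
                    ("AP1", "TEAD", "STAT3"),
                    (label.has_ap1(), label.has_tead(), label.has_stat3()),
                ) if flag
            }
        for _ in range(30):
            present = {m: list(rng.integers(0, 200, rng.integers(0, 3))) for m in motifs}
            base = classify_peak(_profile(**present))
            extra = dict(present)
            m = motifs[rng.integers(0, 4)]
            extra[m] = list(extra.get(m, [])) + [int(rng.integers(0, 200))]
            grown = classify_peak(_profile(**extra))
            assert label_set(base) <= label_set(grown)


class TestPositional:
    def test_hits_at_summit_fill_central_bin(self):
        profiles = [
            PeakMotifProfile(
                "p", {"AP1": [MotifHit(145, "+", 5.0, 1e-5)]}, window_start=0, summit=150
            )
            for _ in range(10)
        ]
        edges, counts = positional_histogram(profiles, "AP1", motif_width=11, window_bp=500, bin_bp=10)
        center_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert counts[center_bin] == 10 and counts.sum() == 10

    def test_uniform_hits_not_rejected_as_uniform(self, rng):
        offsets = rng.integers(-495, 496, size=10_000)
        profiles = [
            PeakMotifProfile(
                f"p{i}", {"AP1": [MotifHit(int(500 + o - 5), "+", 5.0, 1e-5)]},
                window_start=0, summit=500,
            )
            for i, o in enumerate(offsets)
        ]
        edges, counts = positional_histogram(profiles, "AP1", motif_width=11)
        expected = np.full(len(counts), counts.sum() / len(counts))
        chisq = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chisq, df=len(counts) - 1)
        assert p > 0.01

    def test_no_hits_gives_zero_histogram(self):
        edges, counts = positional_histogram([], "AP1", motif_width=11)
        assert counts.sum() == 0


class TestCompositeSpacing:
    def _prof(self, ap1_centers, tead_centers):
        hits = {
            "AP1": [MotifHit(int(150 + c), "+", 5.0, 1e-5) for c in ap1_centers],
            "TEAD_monomer": [MotifHit(int(150 + c), "+", 5.0, 1e-5) for c in tead_centers],
        }
        return PeakMotifProfile("p", hits, window_start=0, summit=150)

    def test_signed_distance(self):
        d = composite_spacing([self._prof([-20], [15])], ap1_width=1,
                              tead_widths={"TEAD_monomer": 1})
        assert d == [35.0]

    def test_overlapping_centers_zero(self):
        assert composite_spacing(
            [self._prof([0], [0])], ap1_width=1, tead_widths={"TEAD_monomer": 1}
        ) == [0.0]

    def test_minimum_magnitude_chosen(self):
        d = composite_spacing(
            [self._prof([0], [15, 90])], ap1_width=1, tead_widths={"TEAD_monomer": 1}
        )
        assert d == [15.0]

    def test_peak_without_both_motifs_skipped(self):
        assert composite_spacing([self._prof([5], [])]) == []
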