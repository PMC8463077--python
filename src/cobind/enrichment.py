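"""Accessibility-matched control sets and chi-square enrichment tests.

Control regions for motif enrichment are DNase hypersensitive sites (DHSs)
sampled to match the accessibility Z-score distribution of the bound DHSs:
Z-scores are binned, and per bin exactly as many non-bound candidates are
drawn (without replacement) as the bound set contains.  Enrichment of a
motif (or motif pair) in target versus control windows is tested with a
Pearson chi-square on the 2x2 table, without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomics import DHSRecord, GenomicInterval, TSSAnnotation
from .motifs import PeakMotifProfile

logger = logging.getLogger("cobind")

__all__ = [
    "ControlSet",
    "EnrichmentResult",
    "CooccurrenceResult",
    "TargetGeneEnrichment",
    "sample_matched_controls",
    "motif_enrichment",
    "enrichment_from_flags",
    "pairwise_cooccurrence",
    "assign_target_genes",
    "target_gene_enrichment",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ControlSet:
    """Z-score-matched, non-intersecting control DHSs."""

    records: List[DHSRecord]
    seed: int
    bin_edges: np.ndarray


@dataclass
class EnrichmentResult:
    motif_name: str
    frac_target: float
    frac_control: float
    fold: float
    chisq: float
    pvalue: float
    infinite_fold: bool = False


@dataclass
class CooccurrenceResult:
    motif_pair: Tuple[str, str]
    frac_target: float
    frac_control: float
    fold: float
    infinite_fold: bool = False


@dataclass
class TargetGeneEnrichment:
    factor: str
    n_diff_target: int
    n_diff_nontarget: int
    n_ctrl_target: int
    n_ctrl_nontarget: int
    chisq: float
    pvalue: float


# ---------------------------------------------------------------------------
# Matched control sampling
# ---------------------------------------------------------------------------

def _interval_tree(intervals: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _intersects(trees: Dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return tree is not None and tree.overlaps(iv.start, iv.end)


def sample_matched_controls(
    bound: Sequence[DHSRecord],
    candidates: Sequence[DHSRecord],
    exclusion: Sequence[GenomicInterval],
    n: Optional[int] = None,
    seed: int = 0,
    bin_width: float = 0.1,
) -> ControlSet:
    """Sample control DHSs matching the bound set's Z-score distribution.

    Z-scores are binned at ``bin_width``; per occupied bin exactly the bound
    set's count is sampled without replacement from candidates that do not
    intersect the exclusion intervals.  Any sampled record that intersects
    the exclusion set is iteratively replaced with an unused candidate from
    the same bin.  Deterministic given ``seed``.
    """
    if n is None:
        n = len(bound)
    if n != len(bound):
        raise ValueError("n must equal the bound set size for exact matching")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rng = np.random.default_rng(seed)
    trees = _interval_tree(exclusion)

    def bin_of(z: float) -> int:
        return int(np.floor(z / bin_width))

    bound_bins: Dict[int, int] = {}
    for rec in bound:
        bound_bins[bin_of(rec.zscore)] = bound_bins.get(bin_of(rec.zscore), 0) + 1

    cand_bins: Dict[int, List[DHSRecord]] = {}
    for rec in candidates:
        b = bin_of(rec.zscore)
        if b in bound_bins:
            cand_bins.setdefault(b, []).append(rec)

    chosen: List[DHSRecord] = []
    for b, need in sorted(bound_bins.items()):
        pool = [r for r in cand_bins.get(b, []) if not _intersects(trees, r.interval)]
        if len(pool) < need:
            raise ValueError(
                f"Z-score bin [{b * bin_width:g}, {(b + 1) * bin_width:g}) has "
                f"{len(pool)} usable candidates but {need} are required "
                f"(shortfall {need - len(pool)})"
            )
        idx = rng.choice(len(pool), size=need, replace=False)
        picked = [pool[i] for i in idx]
        # exclusion was applied up front, but keep the iterative-replacement
        # guarantee explicit: swap out any intersecting record
        unused = [pool[i] for i in range(len(pool)) if i not in set(idx.tolist())]
        for k, rec in enumerate(picked):
            while _intersects(trees, rec.interval):
                if not unused:
                    raise ValueError(
                        f"no replacement candidates left in Z-score bin {b}"
                    )
                rec = unused.pop()
            picked[k] = rec
        chosen.extend(picked)

    lo = min(bound_bins) * bin_width
    hi = (max(bound_bins) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    return ControlSet(records=chosen, seed=seed, bin_edges=edges)


# ---------------------------------------------------------------------------
# Chi-square enrichment
# ---------------------------------------------------------------------------

def _chi_square_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        return 0.0, 1.0
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chisq, pvalue, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chisq), float(pvalue)


def enrichment_from_flags(
    target_has: np.ndarray, control_has: np.ndarray, motif_name: str = ""
) -> EnrichmentResult:
    """Motif enrichment from boolean has-motif flags per target/control peak."""
    target_has = np.asarray(target_has, dtype=bool)
    control_has = np.asarray(control_has, dtype=bool)
    if len(target_has) == 0 or len(control_has) == 0:
        raise ValueError("target and control sets must be non-empty")
    a, b = int(target_has.sum()), int((~target_has).sum())
    c, d = int(control_has.sum()), int((~control_has).sum())
    frac_t = a / (a + b)
    frac_c = c / (c + d)
    infinite = frac_c == 0 and frac_t > 0
    fold = float("inf") if infinite else (frac_t / frac_c if frac_c > 0 else 1.0)
    chisq, pvalue = _chi_square_2x2(a, b, c, d)
    return EnrichmentResult(
        motif_name=motif_name,
        frac_target=frac_t,
        frac_control=frac_c,
        fold=fold,
        chisq=chisq,
        pvalue=pvalue,
        infinite_fold=infinite,
    )


def motif_enrichment(
    target_profiles: Sequence[PeakMotifProfile],
    control_profiles: Sequence[PeakMotifProfile],
    motif_name: str,
) -> EnrichmentResult:
    """Chi-square enrichment of a motif in target vs control windows."""
    t = np.array([p.has_hit(motif_name) for p in target_profiles])
    c = np.array([p.has_hit(motif_name) for p in control_profiles])
    return enrichment_from_flags(t, c, motif_name)


def pairwise_cooccurrence(
    target_profiles: Sequence[PeakMotifProfile],
    control_profiles: Sequence[PeakMotifProfile],
    pair: Tuple[str, str],
) -> CooccurrenceResult:
    """Fold-enrichment of joint motif occurrence in targets vs controls."""
    if len(target_profiles) == 0 or len(control_profiles) == 0:
        raise ValueError("target and control sets must be non-empty")
    m1, m2 = pair
    ft = np.mean([p.has_hit(m1) and p.has_hit(m2) for p in target_profiles])
    fc = np.mean([p.has_hit(m1) and p.has_hit(m2) for p in control_profiles])
    infinite = fc == 0 and ft > 0
    if infinite:
        logger.warning("pair %s/%s absent from controls; fold reported as inf", m1, m2)
    fold = float("inf") if infinite else (float(ft / fc) if fc > 0 else 1.0)
    return CooccurrenceResult(
        motif_pair=pair,
        frac_target=float(ft),
        frac_control=float(fc),
        fold=fold,
        infinite_fold=infinite,
    )


# ---------------------------------------------------------------------------
# Target genes
# ---------------------------------------------------------------------------

def assign_target_genes(
    peaks: Sequence[GenomicInterval],
    tss: TSSAnnotation,
    window_bp: int = 2000,
) -> Dict[str, bool]:
    """gene -> True iff any of its TSSs is within ``window_bp`` of any peak.

    Distance is the gap from the TSS to the nearer peak edge (0 if the TSS
    lies inside the peak); the window is inclusive.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    trees: Dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(0, iv.start - window_bp), iv.end + window_bp
        )
    out: Dict[str, bool] = {}
    for row in tss.entries.itertuples(index=False):
        hit = out.get(row.gene_id, False)
        if not hit:
            tree = trees.get(row.chrom)
            hit = tree is not None and bool(tree.at(row.position))
        out[row.gene_id] = hit
    return out


def target_gene_enrichment(
    diff_genes: Sequence[str],
    all_genes: Sequence[str],
    target_map: Dict[str, bool],
    seed: int = 0,
    factor: str = "",
) -> TargetGeneEnrichment:
    """Chi-square of target-gene fraction: differential vs random control genes.

    The control set is ``len(diff_genes)`` genes sampled uniformly without
    replacement (seeded) from the non-differential remainder of
    ``all_genes``; disjoint sampling keeps the two columns of the 2x2 table
    independent, which is what makes the chi-square null calibrated.
    """
    diff_genes = list(diff_genes)
    all_genes = list(all_genes)
    if not diff_genes:
        raise ValueError("diff_genes must be non-empty")
    if len(all_genes) < 2 * len(diff_genes):
        raise ValueError("need |all_genes| >= 2 * |diff_genes| for a control draw")
    rng = np.random.default_rng(seed)
    pool = sorted(set(all_genes) - set(diff_genes))
    control = [pool[i] for i in rng.choice(len(pool), size=len(diff_genes), replace=False)]
    n_dt = sum(bool(target_map.get(g, False)) for g in diff_genes)
    n_dn = len(diff_genes) - n_dt
    n_ct = sum(bool(target_map.get(g, False)) for g in control)
    n_cn = len(control) - n_ct
    chisq, pvalue = _chi_square_2x2(n_dt, n_dn, n_ct, n_cn)
    return TargetGeneEnrichment(
        factor=factor,
        n_diff_target=n_dt,
        n_diff_nontarget=n_dn,
        n_ctrl_target=n_ct,
        n_ctrl_nontarget=n_cn,
        chisq=chisq,
        pvalue=pvalue,
    )
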