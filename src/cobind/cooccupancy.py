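"""Multi-factor co-occupancy, paralog-specific site calling, and
crosslink-ratio analysis.

Paralog-specific sites (YAP- vs TAZ-specific) are called from replicate
read counts with a negative-binomial Wald test: median-of-ratios size-factor
normalization, method-of-moments dispersion shared across conditions, and
Benjamini-Hochberg adjustment across peaks.  Candidate calls are confirmed
against knockout signal: a genuinely YAP-specific site loses signal only in
the YAP-deletion line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics import Peak

logger = logging.getLogger("cobind")

__all__ = [
    "FactorPeakSet",
    "SummitDistanceSummary",
    "DifferentialBindingResult",
    "KnockoutConfirmation",
    "summit_distance_summary",
    "overlap_fraction",
    "differential_binding",
    "confirm_specific_sites",
    "crosslink_ratio_correlation",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class FactorPeakSet:
    """All peaks of one factor, optionally with per-replicate read counts."""

    factor: str
    peaks: List[Peak]
    replicate_counts: Optional[np.ndarray] = None  # peaks x replicates

    def __post_init__(self) -> None:
        if self.replicate_counts is not None:
            self.replicate_counts = np.asarray(self.replicate_counts)
            if self.replicate_counts.shape[0] != len(self.peaks):
                raise ValueError("replicate count matrix must have one row per peak")

    def trees(self) -> Dict[str, IntervalTree]:
        trees: Dict[str, IntervalTree] = {}
        for i, pk in enumerate(self.peaks):
            trees.setdefault(pk.interval.chrom, IntervalTree()).addi(
                pk.interval.start, pk.interval.end, i
            )
        return trees


@dataclass
class SummitDistanceSummary:
    """Pairwise summit distances between two factors' overlapping peaks."""

    pair: Tuple[str, str]
    distances: np.ndarray
    median: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.distances) and not np.isclose(
            self.median, float(np.median(self.distances))
        ):
            raise ValueError("median inconsistent with distances")


@dataclass
class DifferentialBindingResult:
    peak_id: str
    log2_fold_change: float
    pvalue: float
    padj: float
    call: Literal["YAP_specific", "TAZ_specific", "shared"]


@dataclass
class KnockoutConfirmation:
    peak_id: str
    signal_parent: float
    signal_yapKO: float
    signal_tazKO: float
    confirmed: Literal["YAP_specific", "TAZ_specific", "unconfirmed"]


# ---------------------------------------------------------------------------
# Summit distances and overlap
# ---------------------------------------------------------------------------

def summit_distance_summary(
    setA: FactorPeakSet,
    setB: FactorPeakSet,
    restrict_to_overlap: bool = True,
) -> SummitDistanceSummary:
    """Median |summit - summit| between A peaks and their B partners.

    By default only intersecting peak pairs are considered (co-bound
    regions); with ``restrict_to_overlap=False`` each A peak is paired with
    the nearest B summit on the same chromosome.
    """
    pair = (setA.factor, setB.factor)
    summits_b: Dict[str, np.ndarray] = {}
    for pk in setB.peaks:
        summits_b.setdefault(pk.interval.chrom, []).append(pk.summit)  # type: ignore[arg-type]
    summits_b = {c: np.sort(np.array(v)) for c, v in summits_b.items()}
    trees_b = setB.trees() if restrict_to_overlap else None
    distances: List[float] = []
    for pk in setA.peaks:
        chrom = pk.interval.chrom
        if restrict_to_overlap:
            hits = trees_b.get(chrom, IntervalTree()).overlap(
                pk.interval.start, pk.interval.end
            )
            if not hits:
                continue
            cand = np.array([setB.peaks[h.data].summit for h in hits])
        else:
            cand = summits_b.get(chrom)
            if cand is None or len(cand) == 0:
                continue
        distances.append(float(np.abs(cand - pk.summit).min()))
    if not distances:
        logger.warning("no intersecting peak pairs for %s vs %s", *pair)
        return SummitDistanceSummary(pair, np.empty(0), float("nan"))
    arr = np.array(distances)
    return SummitDistanceSummary(pair, arr, float(np.median(arr)))


def overlap_fraction(setA: FactorPeakSet, setB: FactorPeakSet) -> float:
    """Fraction of A peaks that intersect (>= 1 bp) at least one B peak."""
    if not setA.peaks:
        raise ValueError("overlap fraction undefined for an empty peak set")
    trees_b = setB.trees()
    n = sum(
        1
        for pk in setA.peaks
        if trees_b.get(pk.interval.chrom, IntervalTree()).overlaps(
            pk.interval.start, pk.interval.end
        )
    )
    return n / len(setA.peaks)


# ---------------------------------------------------------------------------
# Differential binding (NB Wald test)
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median ratio to the geometric-mean reference."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    ref = log_counts.mean(axis=1)  # per-peak geometric mean (log scale)
    usable = np.isfinite(ref)
    if not usable.any():
        return np.ones(counts.shape[1])
    ratios = log_counts[usable] - ref[usable, None]
    return np.exp(np.median(ratios, axis=0))


def differential_binding(
    countsA: np.ndarray,
    countsB: np.ndarray,
    peak_ids: Optional[Sequence[str]] = None,
    size_factors: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    dispersion_mode: Literal["moderated", "per_peak"] = "moderated",
    dispersion_floor: float = 1e-8,
) -> List[DifferentialBindingResult]:
    """Per-peak negative-binomial Wald test of factor A (YAP) vs B (TAZ).

    log2 fold change is A over B after size-factor normalization.  The
    dispersion is a method-of-moments estimate from within-condition
    moments, shared across conditions; in the default ``moderated`` mode it
    is floored at the across-peak median to keep the few-replicate Wald
    test calibrated.  Calls: ``YAP_specific`` if log2FC > 0 and
    padj < ``alpha``, ``TAZ_specific`` if log2FC < 0 and padj < ``alpha``,
    otherwise ``shared``.
    """
    countsA = np.asarray(countsA, dtype=float)
    countsB = np.asarray(countsB, dtype=float)
    if countsA.ndim != 2 or countsB.ndim != 2:
        raise ValueError("count matrices must be 2-D (peaks x replicates)")
    if countsA.shape[0] != countsB.shape[0]:
        raise ValueError("count matrices must share the same peak universe")
    if countsA.shape[1] < 2 or countsB.shape[1] < 2:
        raise ValueError("need >= 2 replicates per factor")
    n_peaks = countsA.shape[0]
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(n_peaks)]

    counts = np.hstack([countsA, countsB])
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(counts)
    norm = counts / size_factors
    nA = countsA.shape[1]
    na, nb = norm[:, :nA], norm[:, nA:]

    muA, muB = na.mean(axis=1), nb.mean(axis=1)
    varA = na.var(axis=1, ddof=1)
    varB = nb.var(axis=1, ddof=1)
    # within-condition pooled moments -> shared NB dispersion
    dfA, dfB = na.shape[1] - 1, nb.shape[1] - 1
    pooled_var = (dfA * varA + dfB * varB) / (dfA + dfB)
    pooled_mu = (muA + muB) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mu) / pooled_mu**2
    disp = np.where(np.isfinite(disp), disp, 0.0)
    disp = np.maximum(disp, dispersion_floor)
    if dispersion_mode == "moderated":
        informative = pooled_mu > 0
        if informative.any():
            disp = np.maximum(disp, float(np.median(disp[informative])))
    elif dispersion_mode != "per_peak":
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    eps = 0.5  # pseudo-mean keeps the fold change finite at boundary zeros
    lfc = np.log2((muA + eps) / (muB + eps))
    # delta-method SE of log2(mean) under NB(mu, disp)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_logA = (muA + disp * muA**2) / (na.shape[1] * np.maximum(muA, eps) ** 2)
        var_logB = (muB + disp * muB**2) / (nb.shape[1] * np.maximum(muB, eps) ** 2)
    se = np.sqrt(var_logA + var_logB) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = (countsA.sum(axis=1) + countsB.sum(axis=1)) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    lfc = np.where(all_zero, 0.0, lfc)
    padj = multipletests(pvals, method="fdr_bh")[1]
    padj = np.maximum(padj, pvals)

    results = []
    for i in range(n_peaks):
        if padj[i] < alpha and lfc[i] > 0:
            call = "YAP_specific"
        elif padj[i] < alpha and lfc[i] < 0:
            call = "TAZ_specific"
        else:
            call = "shared"
        results.append(
            DifferentialBindingResult(
                peak_id=str(peak_ids[i]),
                log2_fold_change=float(lfc[i]),
                pvalue=float(pvals[i]),
                padj=float(padj[i]),
                call=call,
            )
        )
    return results


def differential_binding_table(results: Sequence[DifferentialBindingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in results],
            "log2FC": [r.log2_fold_change for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
            "call": [r.call for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Knockout confirmation
# ---------------------------------------------------------------------------

def confirm_specific_sites(
    candidates: Sequence[DifferentialBindingResult],
    signal_parent: Dict[str, float],
    signal_yapKO: Dict[str, float],
    signal_tazKO: Dict[str, float],
    drop_fraction: float = 0.5,
) -> List[KnockoutConfirmation]:
    """Confirm candidate paralog-specific sites against knockout signal.

    A candidate YAP-specific peak is confirmed iff its signal drops below
    ``drop_fraction`` of the parental signal in the YAP knockout while
    staying at or above that fraction in the TAZ knockout (mirrored for
    TAZ-specific candidates).  Shared candidates are never confirmed.
    """
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in (0, 1)")
    out = []
    for cand in candidates:
        pid = cand.peak_id
        parent = float(signal_parent[pid])
        yap_ko = float(signal_yapKO[pid])
        taz_ko = float(signal_tazKO[pid])
        confirmed = "unconfirmed"
        if parent > 0:
            cut = drop_fraction * parent
            if cand.call == "YAP_specific" and yap_ko < cut and taz_ko >= cut:
                confirmed = "YAP_specific"
            elif cand.call == "TAZ_specific" and taz_ko < cut and yap_ko >= cut:
                confirmed = "TAZ_specific"
        out.append(
            KnockoutConfirmation(
                peak_id=pid,
                signal_parent=parent,
                signal_yapKO=yap_ko,
                signal_tazKO=taz_ko,
                confirmed=confirmed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Crosslink-ratio correlation
# ---------------------------------------------------------------------------

def crosslink_ratio_correlation(
    signal1: np.ndarray,
    signal2: np.ndarray,
    motif_scores: np.ndarray,
    epsilon: float = 1.0,
) -> Tuple[np.ndarray, float, bool]:
    """Correlate per-peak log2 signal ratios with motif quality.

    Returns ``(log_ratios, pearson_r, degenerate)``: the per-peak
    ``log2((s1 + eps) / (s2 + eps))`` values, their Pearson correlation with
    the motif scores over peaks with a defined (finite) score, and a flag
    that is True when either variable has zero variance (r reported as 0).
    """
    s1 = np.asarray(signal1, dtype=float)
    s2 = np.asarray(signal2, dtype=float)
    scores = np.asarray(motif_scores, dtype=float)
    if not (len(s1) == len(s2) == len(scores)):
        raise ValueError("signal and score arrays must have equal length")
    log_ratios = np.log2((s1 + epsilon) / (s2 + epsilon))
    defined = np.isfinite(scores) & np.isfinite(log_ratios)
    if defined.sum() < 3:
        raise ValueError("need >= 3 peaks with defined scores")
    x, y = log_ratios[defined], scores[defined]
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in crosslink-ratio correlation; r reported as 0")
        return log_ratios, 0.0, True
    r = float(np.corrcoef(x, y)[0, 1])
    return log_ratios, r, False
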