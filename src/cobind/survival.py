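"""Motif-class gene signatures, gene signature scores, and survival analysis.

The gene signature score (GSS) of a patient is the sum, over signature
genes, of the cohort z-score of that gene's expression:
``GSS_j = sum_i (x_ij - mu_i) / sigma_i`` with the mean and (sample)
standard deviation taken across all patients.  Patients with GSS < 0 form
the low-expression (low-risk) group and patients with GSS >= 0 the
high-expression (high-risk) group.  Survival differences between the groups
are assessed with the product-limit (Kaplan-Meier) estimator and the
two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifClass, PeakMotifProfile

logger = logging.getLogger("cobind")

__all__ = [
    "ExpressionMatrix",
    "SurvivalRecord",
    "GeneSignature",
    "SignatureScoreTable",
    "KMCurve",
    "define_motif_signature",
    "split_by_motif_count",
    "cv_filter",
    "gss",
    "km_estimate",
    "logrank_test",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x patients non-negative expression (TPM-like units)."""

    values: pd.DataFrame  # index: gene ids, columns: patient ids

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values < 0).any().any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def read(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class SurvivalRecord:
    """Follow-up of one patient: time (months) and death indicator."""

    patient: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


def read_survival(path) -> List[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.patient), float(r.time_months), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {
            "patient": [r.patient for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class GeneSignature:
    """A named gene set with a provenance record of how it was defined."""

    name: str
    genes: Set[str]
    definition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError("signature gene set must be non-empty")


@dataclass
class SignatureScoreTable:
    """Per-patient GSS and low/high group (low iff GSS < 0)."""

    table: pd.DataFrame  # columns: gss, group; index: patient ids

    def __post_init__(self) -> None:
        expected = np.where(self.table["gss"] < 0, "low", "high")
        if not (self.table["group"] == expected).all():
            raise ValueError("group labels inconsistent with GSS < 0 rule")

    def patients_in(self, group: str) -> List[str]:
        return list(self.table.index[self.table["group"] == group])


@dataclass
class KMCurve:
    """Product-limit estimate: survival at each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        i = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


# ---------------------------------------------------------------------------
# Signature definition
# ---------------------------------------------------------------------------

SignatureMode = Literal["AP1_only", "TEAD_only", "AP1_and_TEAD"]


def _mode_matches(label: MotifClass, mode: SignatureMode) -> bool:
    # STAT3 content is not part of the AP-1 / TEAD exclusivity rule
    if mode == "AP1_only":
        return label.has_ap1() and not label.has_tead()
    if mode == "TEAD_only":
        return label.has_tead() and not label.has_ap1()
    if mode == "AP1_and_TEAD":
        return label.has_ap1() and label.has_tead()
    raise ValueError(f"unknown signature mode {mode!r}")


def define_motif_signature(
    peak_classes: Dict[str, MotifClass],
    target_map: Dict[str, Set[str]],
    mode: SignatureMode,
) -> GeneSignature:
    """Genes targeted by at least one peak of the requested motif class.

    ``target_map`` maps peak id -> genes with a TSS within the proximity
    window of that peak.  ``AP1_only`` means an AP-1 motif without a TEAD
    motif (STAT3 ignored), and symmetrically for ``TEAD_only``;
    ``AP1_and_TEAD`` requires both.  A gene with several proximal peaks may
    belong to multiple signatures.
    """
    genes: Set[str] = set()
    for peak_id, label in peak_classes.items():
        if _mode_matches(label, mode):
            genes |= set(target_map.get(peak_id, ()))
    if not genes:
        raise ValueError(
            f"no genes for signature mode {mode}; "
            "use a larger dataset or wider proximity window"
        )
    return GeneSignature(
        name=f"signature_{mode}", genes=genes, definition={"mode": mode}
    )


def split_by_motif_count(
    signature: GeneSignature,
    profiles: Dict[str, PeakMotifProfile],
    motif_name: str,
    target_map: Dict[str, Set[str]],
) -> Tuple[Set[str], Set[str]]:
    """Split signature genes by proximal-site motif multiplicity.

    A gene joins ``one_motif_set`` iff some proximal peak has exactly one
    passing hit for ``motif_name`` and ``multi_motif_set`` iff some proximal
    peak has two or more; genes with several proximal peaks may appear in
    both.
    """
    one: Set[str] = set()
    multi: Set[str] = set()
    for peak_id, profile in profiles.items():
        n = profile.n_hits(motif_name)
        if n == 0:
            continue
        genes = set(target_map.get(peak_id, ())) & signature.genes
        if n == 1:
            one |= genes
        else:
            multi |= genes
    return one, multi


# ---------------------------------------------------------------------------
# GSS
# ---------------------------------------------------------------------------

def cv_filter(
    expr: ExpressionMatrix, low: float = 0.05, high: float = 0.85
) -> Set[str]:
    """Retain genes whose coefficient of variation lies in [low, high].

    CV = sample standard deviation (n-1) / mean, across patients.  Genes
    with zero mean are removed.
    """
    if not low < high:
        raise ValueError("low must be < high")
    if expr.values.shape[1] < 2:
        raise ValueError("CV undefined for a single-patient matrix")
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sds / means
    keep = (means > 0) & (cv >= low) & (cv <= high)
    return set(expr.genes[keep])


def gss(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    log_transform: bool = False,
) -> SignatureScoreTable:
    """Gene signature score per patient: sum of cohort z-scores.

    ``log_transform`` applies log2(x + 1) before z-scoring (the default
    scores raw expression).  Errors if a signature gene has zero variance
    (such genes should be removed by ``cv_filter`` first).
    """
    present = sorted(signature.genes & set(expr.genes))
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    missing = signature.genes - set(present)
    if missing:
        logger.warning("%d signature genes absent from matrix", len(missing))
    x = expr.values.loc[present].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sigma == 0):
        bad = [g for g, s in zip(present, sigma.ravel()) if s == 0]
        raise ValueError(
            f"zero-variance signature gene(s) {bad[:5]}; apply cv_filter first"
        )
    scores = ((x - mu) / sigma).sum(axis=0)
    table = pd.DataFrame(
        {"gss": scores, "group": np.where(scores < 0, "low", "high")},
        index=expr.patients,
    )
    return SignatureScoreTable(table)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate.

    At each distinct event time ``t_k``: ``S *= 1 - d_k / n_k`` where
    ``d_k`` counts deaths and ``n_k`` the risk set at ``t_k``.  Ties between
    events and censorings at the same time are resolved events-first
    (censored patients remain in the risk set for that time).
    """
    if not records:
        raise ValueError("need >= 1 survival record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    n = len(records)
    surv, at_risk_list, d_list = [], [], []
    s = 1.0
    for t in event_times:
        n_k = int(np.sum(times >= t))
        d_k = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_k / n_k
        surv.append(s)
        at_risk_list.append(n_k)
        d_list.append(d_k)
    return KMCurve(
        event_times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk_list),
        n_events=np.array(d_list),
    )


def logrank_test(
    groupA: Sequence[SurvivalRecord], groupB: Sequence[SurvivalRecord]
) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed events in group A are compared
    with the hypergeometric expectation given the pooled risk set;
    statistic = (sum O - sum E)^2 / sum V, p from chi-square with 1 df.
    """
    if not groupA or not groupB:
        raise ValueError("both groups must be non-empty")
    tA = np.array([r.time for r in groupA], dtype=float)
    eA = np.array([r.event for r in groupA], dtype=int)
    tB = np.array([r.time for r in groupB], dtype=float)
    eB = np.array([r.event for r in groupB], dtype=int)
    if eA.sum() + eB.sum() == 0:
        raise ValueError("log-rank test requires >= 1 event")
    all_times = np.concatenate([tA, tB])
    all_events = np.concatenate([eA, eB])
    event_times = np.unique(all_times[all_events == 1])
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        n1 = int(np.sum(tA >= t))
        n2 = int(np.sum(tB >= t))
        nt = n1 + n2
        d1 = int(np.sum((tA == t) & (eA == 1)))
        d2 = int(np.sum((tB == t) & (eB == 1)))
        dt = d1 + d2
        if nt < 2 or n1 == 0 or n2 == 0:
            continue
        e1 = dt * n1 / nt
        v = dt * (n1 / nt) * (n2 / nt) * (nt - dt) / (nt - 1)
        O_minus_E += d1 - e1
        V += v
    if V == 0:
        return 0.0, 1.0
    chisq = O_minus_E**2 / V
    return float(chisq), float(stats.chi2.sf(chisq, df=1))
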