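"""End-to-end orchestration: simulate -> summits -> motifs -> ... -> survival.

A run consumes a data directory (either written by the synthetic generator
or arranged in the same layout from real files) and writes every
intermediate as a text table plus a ``manifest.json`` listing parameters,
per-stage seeds and SHA-256 checksums of all outputs.  All stage outputs
are pure functions of (inputs, parameters, seed), so re-running with the
same seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import cooccupancy as co
from . import enrichment as en
from . import genomics as gn
from . import motifs as mo
from . import survival as sv
from .simulate import FACTORS, SyntheticConfig, default_pwms, generate_dataset

logger = logging.getLogger("cobind")

__all__ = ["PipelineParams", "PipelineConfig", "Pipeline", "run_all", "simulate"]

STAGES = (
    "summits",
    "motifs",
    "classify",
    "controls",
    "enrich",
    "cooccupancy",
    "specific",
    "ratios",
    "targets",
    "signature",
    "survive",
)

MOTIF_NAMES = ("AP1", "TEAD_monomer", "TEAD_dimer", "STAT3")


@dataclass
class PipelineParams:
    """Analysis parameters; defaults are the study's printed values."""

    summit_half_width: int = 150
    smoothing_bandwidth_bp: float = 10.0
    tss_window_bp: int = 2000
    upstream_window_bp: int = 150
    motif_pvalue: float = 1e-4
    positional_window_bp: int = 500
    positional_bin_bp: int = 10
    cv_low: float = 0.05
    cv_high: float = 0.85
    padj_cutoff: float = 0.05
    drop_fraction: float = 0.5
    zscore_bin_width: float = 0.1
    log_ratio_epsilon: float = 1.0

    def validate(self) -> None:
        positive = (
            "summit_half_width", "smoothing_bandwidth_bp", "tss_window_bp",
            "upstream_window_bp", "positional_window_bp", "positional_bin_bp",
            "zscore_bin_width",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        if not (0 < self.motif_pvalue < 1):
            raise ValueError("motif_pvalue must be in (0, 1)")
        if not (0 <= self.cv_low < self.cv_high):
            raise ValueError("require 0 <= cv_low < cv_high")
        if not (0 < self.padj_cutoff < 1):
            raise ValueError("padj_cutoff must be in (0, 1)")
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.log_ratio_epsilon < 0:
            raise ValueError("log_ratio_epsilon must be >= 0")


@dataclass
class PipelineConfig:
    data_dir: Path
    out_dir: Path
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)
    factors: Tuple[str, ...] = FACTORS
    reference_factor: str = "YAP"  # peak set used for YAP/TAZ site analyses

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)
        self.params.validate()

    # expected data-directory layout (written by `simulate`)
    def path(self, key: str) -> Path:
        names = {
            "genome": "genome.fa",
            "tss": "tss.tsv",
            "dhs": "dhs_atlas.tsv",
            "counts_YAP": "counts_YAP.tsv",
            "counts_TAZ": "counts_TAZ.tsv",
            "ko": "ko_signals.tsv",
            "expression": "expression.tsv",
            "survival": "survival.tsv",
            "diff_genes": "diff_genes.txt",
        }
        if key in names:
            return self.data_dir / names[key]
        if key.startswith("peaks_"):
            return self.data_dir / f"{key}.narrowPeak"
        if key.startswith("signal_"):
            return self.data_dir / f"{key}.bedGraph"
        if key.startswith("pwm_"):
            return self.data_dir / "pwms" / f"{key[4:]}.txt"
        raise KeyError(key)

    def required_paths(self) -> List[Path]:
        keys = ["genome", "tss", "dhs", "counts_YAP", "counts_TAZ", "ko",
                "expression", "survival", "diff_genes"]
        keys += [f"peaks_{f}" for f in self.factors]
        keys += [f"signal_{f}" for f in self.factors]
        keys += [f"pwm_{m}" for m in MOTIF_NAMES]
        return [self.path(k) for k in keys]

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence((self.seed, idx)).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, **kw) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", **kw)
    return path


class Pipeline:
    """Stage runner; stages cache their in-memory results and write files."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.params = config.params
        missing = [p for p in config.required_paths() if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input file(s): {', '.join(str(m) for m in missing)}"
            )
        config.out_dir.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}
        self.manifest: dict = {
            "seed": config.seed,
            "parameters": dataclasses.asdict(self.params),
            "stages": {},
        }

    # -- helpers ------------------------------------------------------------

    def _record(self, stage: str, outputs: Dict[str, Path]) -> None:
        self.manifest["stages"][stage] = {
            "seed": self.config.stage_seed(stage),
            "outputs": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in outputs.items()},
        }

    def _out(self, name: str) -> Path:
        return self.config.out_dir / name

    @property
    def genome(self):
        if "genome" not in self._cache:
            from pyfaidx import Fasta

            self._cache["genome"] = Fasta(str(self.config.path("genome")))
        return self._cache["genome"]

    def window_sequence(self, chrom: str, start: int, end: int) -> str:
        return str(self.genome[chrom][max(0, start):end]).upper()

    @property
    def pwms(self) -> Dict[str, mo.PositionWeightMatrix]:
        if "pwms" not in self._cache:
            self._cache["pwms"] = {
                m: mo.PositionWeightMatrix.read_probs(self.config.path(f"pwm_{m}"))
                for m in MOTIF_NAMES
            }
        return self._cache["pwms"]

    @property
    def thresholds(self) -> Dict[str, float]:
        if "thresholds" not in self._cache:
            self._cache["thresholds"] = {
                m: mo.score_threshold_from_pvalue(pwm, self.params.motif_pvalue)
                for m, pwm in self.pwms.items()
            }
        return self._cache["thresholds"]

    @property
    def tss(self) -> gn.TSSAnnotation:
        if "tss" not in self._cache:
            self._cache["tss"] = gn.TSSAnnotation.read(self.config.path("tss"))
        return self._cache["tss"]

    # -- stages -------------------------------------------------------------

    def stage_summits(self) -> Dict[str, List[gn.Peak]]:
        """Recompute summits from smoothed signal for every factor."""
        if "summits" in self._cache:
            return self._cache["summits"]
        out: Dict[str, List[gn.Peak]] = {}
        outputs: Dict[str, Path] = {}
        for factor in self.config.factors:
            intervals = gn.read_intervals(
                self.config.path(f"peaks_{factor}"), dialect="narrowPeak"
            )
            signal = gn.read_bedgraph(self.config.path(f"signal_{factor}"))
            peaks = []
            for iv in intervals:
                track = signal.track(iv.chrom, iv.start, iv.end)
                smoothed = gn.smooth_signal(track, self.params.smoothing_bandwidth_bp)
                peaks.append(gn.find_summit(iv, smoothed))
            out[factor] = peaks
            path = self._out(f"summits_{factor}.narrowPeak")
            ivs = [
                gn.GenomicInterval(
                    p.interval.chrom, p.interval.start, p.interval.end,
                    name=p.interval.name, summit=p.summit,
                )
                for p in peaks
            ]
            gn.write_intervals(ivs, path, dialect="narrowPeak")
            outputs[factor] = path
        self._record("summits", outputs)
        self._cache["summits"] = out
        return out

    @property
    def reference_peaks(self) -> List[gn.Peak]:
        return self.stage_summits()[self.config.reference_factor]

    @property
    def summit_windows(self) -> List[gn.GenomicInterval]:
        return gn.adjust_to_summit_window(
            self.reference_peaks, self.params.summit_half_width
        )

    def stage_motifs(self) -> List[mo.PeakMotifProfile]:
        """Scan summit windows of the reference peak set with every PWM."""
        if "profiles" in self._cache:
            return self._cache["profiles"]
        self.stage_summits()
        profiles = []
        for pk, win in zip(self.reference_peaks, self.summit_windows):
            seq = self.window_sequence(win.chrom, win.start, win.end)
            profiles.append(
                mo.profile_peak(
                    pk.interval.name or f"{win.chrom}:{win.start}",
                    seq,
                    self.pwms,
                    self.thresholds,
                    window_start=win.start,
                    summit=pk.summit,
                )
            )
        rows = []
        for p in profiles:
            row = {"peak_id": p.peak_id, "summit": p.summit}
            for m in MOTIF_NAMES:
                row[f"n_hits_{m}"] = p.n_hits(m)
                row[f"best_score_{m}"] = p.best_score.get(m, np.nan)
            rows.append(row)
        path = _write_tsv(pd.DataFrame(rows), self._out("motif_profiles.tsv"))
        self._record("motifs", {"profiles": path})
        self._cache["profiles"] = profiles
        return profiles

    def stage_classify(self) -> Dict[str, mo.MotifClass]:
        if "classes" in self._cache:
            return self._cache["classes"]
        profiles = self.stage_motifs()
        classes = {p.peak_id: mo.classify_peak(p) for p in profiles}
        df = pd.DataFrame(
            {"peak_id": list(classes), "class_label": [c.value for c in classes.values()]}
        )
        path = _write_tsv(df, self._out("peak_classes.tsv"))
        self._record("classify", {"classes": path})
        self._cache["classes"] = classes
        return classes

    def _read_dhs(self) -> List[gn.DHSRecord]:
        if "dhs" not in self._cache:
            df = pd.read_csv(
                self.config.path("dhs"), sep="\t", header=None,
                names=["chrom", "start", "end", "name", "zscore"],
            )
            self._cache["dhs"] = [
                gn.DHSRecord(
                    gn.GenomicInterval(r.chrom, r.start, r.end, name=r.name), r.zscore
                )
                for r in df.itertuples(index=False)
            ]
        return self._cache["dhs"]

    def stage_controls(self) -> en.ControlSet:
        """Accessibility-matched, non-intersecting control DHS set."""
        if "controls" in self._cache:
            return self._cache["controls"]
        self.stage_summits()
        atlas = self._read_dhs()
        peak_ivs = [p.interval for p in self.reference_peaks]
        from intervaltree import IntervalTree

        trees: Dict[str, IntervalTree] = {}
        for iv in peak_ivs:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        bound = [
            r for r in atlas
            if r.interval.chrom in trees
            and trees[r.interval.chrom].overlaps(r.interval.start, r.interval.end)
        ]
        if not bound:
            raise ValueError("no DHS records intersect the reference peak set")
        controls = en.sample_matched_controls(
            bound,
            atlas,
            peak_ivs,
            seed=self.config.stage_seed("controls"),
            bin_width=self.params.zscore_bin_width,
        )
        path = self._out("control_dhs.bed")
        gn.write_intervals([r.interval for r in controls.records], path)
        sidecar = self._out("control_dhs.json")
        sidecar.write_text(
            json.dumps(
                {
                    "seed": controls.seed,
                    "bin_width": self.params.zscore_bin_width,
                    "n": len(controls.records),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        self._record("controls", {"bed": path, "sidecar": sidecar})
        self._cache["controls"] = controls
        self._cache["bound_dhs"] = bound
        return controls

    def _control_profiles(self) -> List[mo.PeakMotifProfile]:
        if "control_profiles" not in self._cache:
            controls = self.stage_controls()
            hw = self.params.summit_half_width
            profiles = []
            for rec in controls.records:
                iv = rec.interval
                center = (iv.start + iv.end) // 2
                start = max(0, center - hw)
                seq = self.window_sequence(iv.chrom, start, center + hw + 1)
                profiles.append(
                    mo.profile_peak(
                        iv.name or f"{iv.chrom}:{iv.start}", seq, self.pwms,
                        self.thresholds, window_start=start, summit=center,
                    )
                )
            self._cache["control_profiles"] = profiles
        return self._cache["control_profiles"]

    def stage_enrich(self) -> pd.DataFrame:
        """Motif and motif-pair enrichment vs matched controls."""
        if "enrich" in self._cache:
            return self._cache["enrich"]
        target = self.stage_motifs()
        control = self._control_profiles()
        rows = []
        for m in MOTIF_NAMES:
            r = en.motif_enrichment(target, control, m)
            rows.append(
                {
                    "motif": m,
                    "frac_target": r.frac_target,
                    "frac_control": r.frac_control,
                    "fold": r.fold,
                    "chisq": r.chisq,
                    "pvalue": r.pvalue,
                }
            )
        enrich_df = pd.DataFrame(rows)
        pairs = [("AP1", "TEAD_monomer"), ("AP1", "STAT3"), ("TEAD_monomer", "STAT3")]
        pair_rows = []
        for pair in pairs:
            r = en.pairwise_cooccurrence(target, control, pair)
            pair_rows.append(
                {
                    "motif_a": pair[0],
                    "motif_b": pair[1],
                    "frac_target": r.frac_target,
                    "frac_control": r.frac_control,
                    "fold": r.fold if np.isfinite(r.fold) else np.inf,
                }
            )
        pair_df = pd.DataFrame(pair_rows)
        p1 = _write_tsv(enrich_df, self._out("motif_enrichment.tsv"))
        p2 = _write_tsv(pair_df, self._out("motif_cooccurrence.tsv"))
        self._record("enrich", {"enrichment": p1, "cooccurrence": p2})
        self._cache["enrich"] = enrich_df
        return enrich_df

    def stage_cooccupancy(self) -> pd.DataFrame:
        """Pairwise summit distances and overlap fractions between factors."""
        if "cooccupancy" in self._cache:
            return self._cache["cooccupancy"]
        summits = self.stage_summits()
        sets = {
            f: co.FactorPeakSet(factor=f, peaks=pks) for f, pks in summits.items()
        }
        rows = []
        factors = list(self.config.factors)
        for i, a in enumerate(factors):
            for b in factors[i + 1 :]:
                sd = co.summit_distance_summary(sets[a], sets[b])
                rows.append(
                    {
                        "factor_a": a,
                        "factor_b": b,
                        "n_pairs": len(sd.distances),
                        "median_summit_distance_bp": sd.median,
                        "overlap_fraction": co.overlap_fraction(sets[a], sets[b]),
                    }
                )
        df = pd.DataFrame(rows)
        path = _write_tsv(df, self._out("summit_distances.tsv"))
        self._record("cooccupancy", {"distances": path})
        self._cache["cooccupancy"] = df
        return df

    def stage_specific(self) -> pd.DataFrame:
        """YAP- vs TAZ-specific site calls plus knockout confirmation."""
        if "specific" in self._cache:
            return self._cache["specific"]
        cy = pd.read_csv(self.config.path("counts_YAP"), sep="\t", index_col=0)
        ct = pd.read_csv(self.config.path("counts_TAZ"), sep="\t", index_col=0)
        results = co.differential_binding(
            cy.to_numpy(), ct.to_numpy(), peak_ids=list(cy.index),
            alpha=self.params.padj_cutoff,
        )
        ko = pd.read_csv(self.config.path("ko"), sep="\t").set_index("peak_id")
        confirmations = co.confirm_specific_sites(
            results,
            ko["parent"].to_dict(),
            ko["yapKO"].to_dict(),
            ko["tazKO"].to_dict(),
            drop_fraction=self.params.drop_fraction,
        )
        df = co.differential_binding_table(results)
        df["confirmed"] = [c.confirmed for c in confirmations]
        path = _write_tsv(df, self._out("specific_sites.tsv"))
        self._record("specific", {"specific": path})
        self._cache["specific"] = df
        return df

    def stage_ratios(self) -> Dict[str, float]:
        """JUNB:TEAD crosslink log-ratio vs AP-1 / TEAD motif quality."""
        if "ratios" in self._cache:
            return self._cache["ratios"]
        profiles = self.stage_motifs()
        junb = gn.read_bedgraph(self.config.path("signal_JUNB"))
        tead = gn.read_bedgraph(self.config.path("signal_TEAD"))
        s1, s2 = [], []
        for pk in self.reference_peaks:
            iv = pk.interval
            s1.append(junb.values(iv.chrom, iv.start, iv.end).mean())
            s2.append(tead.values(iv.chrom, iv.start, iv.end).mean())
        s1, s2 = np.array(s1), np.array(s2)
        out = {}
        ratio_df = pd.DataFrame({"peak_id": [p.peak_id for p in profiles]})
        for motif in ("AP1", "TEAD_monomer"):
            scores = np.array([p.best_score.get(motif, np.nan) for p in profiles])
            log_ratios, r, degenerate = co.crosslink_ratio_correlation(
                s1, s2, scores, epsilon=self.params.log_ratio_epsilon
            )
            out[f"pearson_r_{motif}"] = r
            ratio_df[f"score_{motif}"] = scores
            if "log2_ratio" not in ratio_df:
                ratio_df["log2_ratio"] = log_ratios
        p1 = _write_tsv(ratio_df, self._out("crosslink_ratios.tsv"))
        p2 = self._out("crosslink_correlation.json")
        p2.write_text(json.dumps({k: round(v, 6) for k, v in out.items()},
                                 indent=2, sort_keys=True) + "\n")
        self._record("ratios", {"ratios": p1, "correlation": p2})
        self._cache["ratios"] = out
        return out

    def stage_targets(self) -> pd.DataFrame:
        """Target-gene assignment and differential-gene enrichment."""
        if "targets" in self._cache:
            return self._cache["targets"]
        self.stage_summits()
        target_map = en.assign_target_genes(
            self.summit_windows, self.tss, self.params.tss_window_bp
        )
        diff_genes = [
            g.strip()
            for g in self.config.path("diff_genes").read_text().splitlines()
            if g.strip()
        ]
        all_genes = sorted(self.tss.entries["gene_id"].unique())
        enr = en.target_gene_enrichment(
            diff_genes, all_genes, target_map,
            seed=self.config.stage_seed("targets"),
            factor=self.config.reference_factor,
        )
        labels = gn.classify_tss_proximity(
            [p.interval for p in self.reference_peaks], self.tss,
            self.params.tss_window_bp,
        )
        prox = pd.DataFrame(
            {
                "peak_id": [p.interval.name for p in self.reference_peaks],
                "tss_proximity": [labels[i] for i in range(len(self.reference_peaks))],
            }
        )
        upstream_frac = gn.upstream_window_fraction(
            self.reference_peaks, self.tss, self.params.upstream_window_bp
        )
        prox_path = _write_tsv(prox, self._out("tss_proximity.tsv"))
        tg = pd.DataFrame(
            {"gene_id": sorted(target_map), "is_target": [target_map[g] for g in sorted(target_map)]}
        )
        p1 = _write_tsv(tg, self._out("target_genes.tsv"))
        df = pd.DataFrame(
            [
                {
                    "factor": enr.factor,
                    "n_diff_target": enr.n_diff_target,
                    "n_diff_nontarget": enr.n_diff_nontarget,
                    "n_ctrl_target": enr.n_ctrl_target,
                    "n_ctrl_nontarget": enr.n_ctrl_nontarget,
                    "chisq": enr.chisq,
                    "pvalue": enr.pvalue,
                    "upstream_summit_fraction": upstream_frac,
                }
            ]
        )
        p2 = _write_tsv(df, self._out("target_gene_enrichment.tsv"))
        self._record("targets", {"target_genes": p1, "enrichment": p2,
                                 "tss_proximity": prox_path})
        self._cache["targets"] = df
        self._cache["target_map"] = target_map
        return df

    def _peak_gene_map(self) -> Dict[str, Set[str]]:
        """peak id -> genes with a TSS within the proximity window."""
        if "peak_gene_map" not in self._cache:
            window = self.params.tss_window_bp
            by_chrom = {}
            for c, g in self.tss.entries.groupby("chrom", sort=False):
                order = np.argsort(g["position"].to_numpy())
                by_chrom[c] = (
                    g["position"].to_numpy()[order],
                    g["gene_id"].to_numpy()[order],
                )
            out: Dict[str, Set[str]] = {}
            for pk, win in zip(self.reference_peaks, self.summit_windows):
                pid = pk.interval.name
                positions_genes = by_chrom.get(win.chrom)
                genes: Set[str] = set()
                if positions_genes is not None:
                    pos, gid = positions_genes
                    lo = int(np.searchsorted(pos, win.start - window, side="left"))
                    hi = int(np.searchsorted(pos, win.end - 1 + window, side="right"))
                    genes = set(gid[lo:hi])
                out[pid] = genes
            self._cache["peak_gene_map"] = out
        return self._cache["peak_gene_map"]

    def stage_signature(self) -> Dict[str, sv.GeneSignature]:
        """Motif-class gene signatures from classified peaks."""
        if "signatures" in self._cache:
            return self._cache["signatures"]
        classes = self.stage_classify()
        peak_genes = self._peak_gene_map()
        signatures: Dict[str, sv.GeneSignature] = {}
        outputs: Dict[str, Path] = {}
        for mode in ("AP1_only", "TEAD_only", "AP1_and_TEAD"):
            try:
                sig = sv.define_motif_signature(classes, peak_genes, mode)
            except ValueError:
                logger.warning("signature %s is empty; skipped", mode)
                continue
            signatures[mode] = sig
            path = self._out(f"signature_{mode}.txt")
            path.write_text("\n".join(sorted(sig.genes)) + "\n")
            sidecar = self._out(f"signature_{mode}.json")
            sidecar.write_text(
                json.dumps(
                    {"mode": mode, "n_genes": len(sig.genes)}, indent=2, sort_keys=True
                )
                + "\n"
            )
            outputs[mode] = path
            outputs[f"{mode}_meta"] = sidecar
        self._record("signature", outputs)
        self._cache["signatures"] = signatures
        return signatures

    def stage_survive(self) -> pd.DataFrame:
        """GSS stratification + Kaplan-Meier / log-rank per signature."""
        if "survive" in self._cache:
            return self._cache["survive"]
        signatures = self.stage_signature()
        expr = sv.ExpressionMatrix.read(self.config.path("expression"))
        records = sv.read_survival(self.config.path("survival"))
        rec_by_patient = {r.patient: r for r in records}
        retained = sv.cv_filter(expr, self.params.cv_low, self.params.cv_high)
        rows = []
        outputs: Dict[str, Path] = {}
        for mode, sig in signatures.items():
            genes = sig.genes & retained
            if not genes:
                logger.warning("signature %s empty after CV filter", mode)
                continue
            filtered = sv.GeneSignature(sig.name, genes, sig.definition)
            table = sv.gss(expr, filtered)
            low = [rec_by_patient[p] for p in table.patients_in("low") if p in rec_by_patient]
            high = [rec_by_patient[p] for p in table.patients_in("high") if p in rec_by_patient]
            if not low or not high:
                logger.warning("signature %s: one-sided stratification; skipped", mode)
                continue
            stat, pvalue = sv.logrank_test(high, low)
            km_high, km_low = sv.km_estimate(high), sv.km_estimate(low)
            horizon = float(
                np.median([r.time for r in records]) if records else 0.0
            )
            rows.append(
                {
                    "signature": mode,
                    "n_genes": len(genes),
                    "n_low": len(low),
                    "n_high": len(high),
                    "logrank_chisq": stat,
                    "logrank_p": pvalue,
                    "surv_high_at_median_t": km_high.survival_at(horizon),
                    "surv_low_at_median_t": km_low.survival_at(horizon),
                }
            )
            for grp, curve in (("high", km_high), ("low", km_low)):
                path = _write_tsv(curve.as_frame(), self._out(f"km_{mode}_{grp}.tsv"))
                outputs[f"km_{mode}_{grp}"] = path
            path = _write_tsv(
                table.table.reset_index(names="patient"), self._out(f"gss_{mode}.tsv")
            )
            outputs[f"gss_{mode}"] = path
        df = pd.DataFrame(rows)
        path = _write_tsv(df, self._out("survival_results.tsv"))
        outputs["results"] = path
        self._record("survive", outputs)
        self._cache["survive"] = df
        return df

    # -- driver -------------------------------------------------------------

    def run_all(self) -> dict:
        """Execute every stage in order and write the manifest."""
        stage_fns = {
            "summits": self.stage_summits,
            "motifs": self.stage_motifs,
            "classify": self.stage_classify,
            "controls": self.stage_controls,
            "enrich": self.stage_enrich,
            "cooccupancy": self.stage_cooccupancy,
            "specific": self.stage_specific,
            "ratios": self.stage_ratios,
            "targets": self.stage_targets,
            "signature": self.stage_signature,
            "survive": self.stage_survive,
        }
        for stage in STAGES:
            t0 = time.time()
            try:
                stage_fns[stage]()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1f s", stage, time.time() - t0)
        manifest_path = self.config.out_dir / "manifest.json"
        manifest_path.write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        return self.manifest


def simulate(seed: int, data_dir, config: Optional[SyntheticConfig] = None) -> Dict[str, Path]:
    """Generate a synthetic dataset (plus PWM files) into ``data_dir``."""
    if config is None:
        config = SyntheticConfig(seed=seed)
    else:
        config = dataclasses.replace(config, seed=seed)
    dataset = generate_dataset(config)
    files = dataset.write(data_dir)
    pwm_dir = Path(data_dir) / "pwms"
    pwm_dir.mkdir(exist_ok=True)
    for name, pwm in default_pwms().items():
        pwm.write_probs(pwm_dir / f"{name}.txt")
        files[f"pwm_{name}"] = pwm_dir / f"{name}.txt"
    cfg_path = Path(data_dir) / "config.json"
    cfg_path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    files["config"] = cfg_path
    return files


def run_all(config: PipelineConfig) -> dict:
    return Pipeline(config).run_all()
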