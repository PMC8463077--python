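"""Genomic intervals, signal tracks, summit calling, and TSS proximity.

All coordinates are 0-based half-open (BED convention).  narrowPeak summit
offsets (column 10) are converted to absolute positions on read; an offset of
-1 means "no summit recorded".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger("cobind")

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "SignalTrackSet",
    "TSSAnnotation",
    "DHSRecord",
    "read_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
    "smooth_signal",
    "find_summit",
    "adjust_to_summit_window",
    "classify_tss_proximity",
    "upstream_window_fraction",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``summit`` is the optional absolute coordinate of the signal maximum
    (populated from narrowPeak column 10 when present).
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def intersects(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Gap to a point; 0 if the point lies inside the interval."""
        if self.start <= pos < self.end:
            return 0
        return max(self.start - pos, pos - (self.end - 1))


@dataclass
class Peak:
    """A called peak: an interval, a summit, and per-factor mean signal."""

    interval: GenomicInterval
    summit: int
    signal: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )


@dataclass
class SignalTrack:
    """Per-base non-negative signal starting at ``origin`` on ``chrom``."""

    chrom: str
    origin: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if np.any(self.values < 0):
            raise ValueError("signal values must be >= 0")

    @property
    def end(self) -> int:
        return self.origin + len(self.values)

    def covers(self, interval: GenomicInterval) -> bool:
        return (
            interval.chrom == self.chrom
            and interval.start >= self.origin
            and interval.end <= self.end
        )


class SignalTrackSet:
    """Sparse per-chromosome signal (bedGraph semantics; gaps are zero)."""

    def __init__(self) -> None:
        self._pending: dict = {}
        self._arrays: dict = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        self._pending.setdefault(chrom, []).append((start, end, value))
        self._arrays.pop(chrom, None)

    def add_arrays(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> None:
        self._pending.setdefault(chrom, []).extend(
            zip(starts.tolist(), ends.tolist(), values.tolist())
        )
        self._arrays.pop(chrom, None)

    def finalize(self) -> "SignalTrackSet":
        for chrom, segs in self._pending.items():
            segs.sort()
            self._arrays[chrom] = (
                np.array([s[0] for s in segs], dtype=np.int64),
                np.array([s[1] for s in segs], dtype=np.int64),
                np.array([s[2] for s in segs], dtype=float),
            )
        return self

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)``; 0 where uncovered."""
        if chrom in self._pending and chrom not in self._arrays:
            self.finalize()
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._arrays:
            return out
        starts, ends, vals = self._arrays[chrom]
        lo = max(0, int(np.searchsorted(starts, start, side="right")) - 1)
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a, b = max(int(starts[i]), start), min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] += vals[i]
        return out

    def track(self, chrom: str, start: int, end: int) -> SignalTrack:
        return SignalTrack(chrom, start, self.values(chrom, start, end))


@dataclass
class TSSAnnotation:
    """Transcription start sites: (gene_id, chrom, tss_position, strand)."""

    entries: pd.DataFrame

    COLUMNS = ("gene_id", "chrom", "position", "strand")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries, columns=list(self.COLUMNS))
        if (df["position"] < 0).any():
            raise ValueError("tss_position must be >= 0")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand value(s): {df.loc[bad, 'strand'].unique()}")
        self.entries = df

    @classmethod
    def read(cls, path) -> "TSSAnnotation":
        df = pd.read_csv(
            path, sep="\t", names=list(cls.COLUMNS), header=None, comment="#"
        )
        return cls(df)

    def write(self, path) -> None:
        self.entries.to_csv(path, sep="\t", header=False, index=False)

    def by_chrom(self) -> dict:
        return {c: g for c, g in self.entries.groupby("chrom", sort=False)}


@dataclass
class DHSRecord:
    """A DNase I hypersensitive site with an accessibility Z-score."""

    interval: GenomicInterval
    zscore: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.zscore):
            raise ValueError("zscore must be finite")


# ---------------------------------------------------------------------------
# Interval I/O
# ---------------------------------------------------------------------------

def read_intervals(
    path, dialect: Literal["bed", "narrowPeak"] = "bed"
) -> list:
    """Read BED3/BED6 or narrowPeak intervals.

    narrowPeak column 10 (summit offset from start) is converted to an
    absolute ``summit``; an offset of -1 leaves the summit unset.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            summit = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}: narrowPeak line {lineno} has {len(fields)} columns, expected 10"
                    )
                offset = int(fields[9])
                if offset >= 0:
                    summit = start + offset
            try:
                out.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, summit=summit)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path,
    dialect: Literal["bed", "narrowPeak"] = "bed",
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            if dialect == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")
            else:
                offset = iv.summit - iv.start if iv.summit is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\t0\t-1\t-1\t{offset}\n"
                )


def read_bedgraph(path) -> SignalTrackSet:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed bedGraph: {exc}") from exc
    ts = SignalTrackSet()
    for chrom, g in df.groupby("chrom", sort=False):
        ts.add_arrays(
            str(chrom),
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["value"].to_numpy(),
        )
    return ts.finalize()


def write_bedgraph(tracks: Iterable[SignalTrack], path, precision: int = 4) -> None:
    """Write per-base tracks as run-length-merged bedGraph lines."""
    with open(path, "w") as fh:
        for tr in tracks:
            vals = np.round(tr.values, precision)
            if len(vals) == 0:
                continue
            # run-length encode consecutive equal values
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            rows = [
                f"{tr.chrom}\t{tr.origin + s}\t{tr.origin + e}\t{vals[s]:.{precision}g}"
                for s, e in zip(starts, ends)
                if vals[s] != 0
            ]
            if rows:
                fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Smoothing and summits
# ---------------------------------------------------------------------------

def smooth_signal(track: SignalTrack, bandwidth_bp: float = 10.0) -> SignalTrack:
    """Gaussian-smooth a signal track.

    The kernel standard deviation is ``bandwidth_bp`` (default 10 bp), the
    kernel is truncated at +/-4 sigma and renormalised to sum 1, and the
    output has the same length as the input (reflected boundaries).
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth_bp must be > 0")
    if len(track.values) == 0:
        raise ValueError("cannot smooth an empty track")
    smoothed = gaussian_filter1d(track.values, sigma=bandwidth_bp, truncate=4.0, mode="reflect")
    return SignalTrack(track.chrom, track.origin, np.clip(smoothed, 0.0, None))


def find_summit(peak: GenomicInterval, track: SignalTrack) -> Peak:
    """Locate the peak summit: the position of maximal signal in the peak.

    Ties break to the smallest coordinate.  An all-zero signal keeps the
    peak start as the summit and logs a warning.
    """
    if not track.covers(peak):
        raise ValueError(
            f"track [{track.origin}, {track.end}) on {track.chrom} does not cover "
            f"peak {peak.chrom}:[{peak.start}, {peak.end})"
        )
    window = track.values[peak.start - track.origin : peak.end - track.origin]
    if np.all(window == 0):
        logger.warning(
            "peak %s:[%d, %d) has all-zero signal; summit set to start",
            peak.chrom, peak.start, peak.end,
        )
        summit = peak.start
    else:
        summit = peak.start + int(np.argmax(window))  # argmax: first max wins
    return Peak(interval=peak, summit=summit)


def adjust_to_summit_window(
    peaks: Sequence[Peak], half_width: int = 150
) -> list:
    """Replace each peak by its summit +/- ``half_width`` window.

    Windows are inclusive on both ends (length ``2*half_width + 1``) and
    clipped at coordinate 0.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    out = []
    for pk in peaks:
        start = max(0, pk.summit - half_width)
        end = pk.summit + half_width + 1
        out.append(
            GenomicInterval(pk.interval.chrom, start, end, name=pk.interval.name)
        )
    return out


# ---------------------------------------------------------------------------
# TSS proximity
# ---------------------------------------------------------------------------

def _min_tss_distance(iv: GenomicInterval, positions: np.ndarray) -> int:
    """Minimum edge distance from an interval to sorted TSS positions."""
    i = int(np.searchsorted(positions, iv.start))
    best = None
    for j in (i - 1, i, int(np.searchsorted(positions, iv.end))):
        if 0 <= j < len(positions):
            d = iv.distance_to_point(int(positions[j]))
            best = d if best is None else min(best, d)
    # also check any TSS inside [start, end)
    k = int(np.searchsorted(positions, iv.end - 1, side="right"))
    if i < k:
        return 0
    return best if best is not None else np.iinfo(np.int64).max


def classify_tss_proximity(
    peaks: Sequence[GenomicInterval],
    tss: TSSAnnotation,
    window_bp: int = 2000,
) -> dict:
    """Label each peak ``proximal`` (within ``window_bp`` of any TSS) or ``distal``.

    Distance is 0 if a TSS lies inside the peak, else the gap to the nearer
    edge; the window is inclusive ("within 2 kb").
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if len(tss.entries) == 0:
        logger.warning("empty TSS annotation: all peaks labeled distal")
        return {i: "distal" for i in range(len(peaks))}
    pos_by_chrom = {
        c: np.sort(g["position"].to_numpy())
        for c, g in tss.entries.groupby("chrom", sort=False)
    }
    labels = {}
    for i, iv in enumerate(peaks):
        positions = pos_by_chrom.get(iv.chrom)
        if positions is None:
            labels[i] = "distal"
            continue
        d = _min_tss_distance(iv, positions)
        labels[i] = "proximal" if d <= window_bp else "distal"
    return labels


def upstream_window_fraction(
    peaks: Sequence[Peak],
    tss: TSSAnnotation,
    upstream_bp: int = 150,
) -> float:
    """Fraction of peaks whose summit is within ``upstream_bp`` upstream of a TSS.

    Upstream is lower coordinates for a + strand TSS and higher coordinates
    for a - strand TSS; the summit must lie in ``[tss - upstream_bp, tss]``
    (mirrored for -) for at least one TSS.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if len(peaks) == 0:
        return 0.0
    groups = {}
    for c, g in tss.entries.groupby(["chrom", "strand"], sort=False):
        groups[c] = np.sort(g["position"].to_numpy())
    n_hit = 0
    for pk in peaks:
        s = pk.summit
        chrom = pk.interval.chrom
        hit = False
        plus = groups.get((chrom, "+"))
        if plus is not None:
            # need a TSS t with s <= t <= s + upstream_bp
            j = int(np.searchsorted(plus, s, side="left"))
            if j < len(plus) and plus[j] <= s + upstream_bp:
                hit = True
        if not hit:
            minus = groups.get((chrom, "-"))
            if minus is not None:
                # need a TSS t with s - upstream_bp <= t <= s
                j = int(np.searchsorted(minus, s, side="right")) - 1
                if j >= 0 and minus[j] >= s - upstream_bp:
                    hit = True
        n_hit += hit
    return n_hit / len(peaks)
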