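"""Genomic interval sets, coverage tracks and peak-centered matrices.

Downstream ChIP-seq quantification on standard text formats: BED peak sets
(0-based, half-open), bedGraph coverage tracks (gaps read as zero coverage),
reciprocal peak-overlap percentages via a sorted sweep, and log2-transformed
coverage matrices centered on peak midpoints with composite (column-mean)
profiles — the heatmap/metagene constructions used to compare a protein's
enrichment around another factor's binding sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class BedParseError(ValueError):
    """A BED/bedGraph file violates the format contract."""


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/touching-by-overlap sorted intervals (half-open)."""
    if starts.size == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s < out_e[-1]:  # strict: [0,10) and [10,20) stay separate
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


@dataclass
class PeakSet:
    """A labelled set of genomic intervals, sorted by (chromosome, start).

    Overlapping intervals within the set are merged on construction (unless
    ``merge=False``) so that "percentage of peaks" is well-defined.
    """

    intervals: pd.DataFrame
    label: str = ""
    merge: bool = True

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            raise ValueError("interval with start >= end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        if self.merge and len(df):
            merged = []
            for chrom, grp in df.groupby("chrom", sort=True):
                s, e = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
                merged.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
            df = pd.concat(merged, ignore_index=True)
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
            for chrom, grp in self.intervals.groupby("chrom", sort=True)
        }

    @property
    def midpoints(self) -> pd.DataFrame:
        """Peak midpoints, floor((start + end) / 2), one row per peak."""
        df = self.intervals
        return pd.DataFrame(
            {"chrom": df["chrom"], "mid": (df["start"] + df["end"]) // 2}
        )


@dataclass
class CoverageTrack:
    """Piecewise-constant nonnegative coverage over 0-based half-open intervals.

    Positions not covered by any interval have coverage zero.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (starts, ends, values) in self.data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="mergesort")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts < 0) or np.any(starts >= ends):
                raise ValueError(f"{chrom}: invalid interval coordinates")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping coverage intervals")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage")
            clean[chrom] = (starts, ends, values)
        self.data = clean

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp coverage over [start, end); out-of-track bp are 0.

        ``start`` may be negative and ``end`` may exceed the covered extent;
        such positions are filled with zero.
        """
        if end <= start:
            raise ValueError("empty window")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            out[a:b] = values[i]
        return out


def read_bed(path: str | Path, label: str | None = None, merge: bool = True) -> PeakSet:
    """Read a BED3+ file into a sorted (and by default merged) PeakSet."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            rows.append({"chrom": chrom, "start": start, "end": end})
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(frame, label=label or path.stem, merge=merge)


def write_bed(peaks: PeakSet, path: str | Path) -> Path:
    path = Path(path)
    peaks.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph file; uncovered positions are implicitly zero."""
    path = Path(path)
    per_chrom: dict[str, list[list]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed record") from exc
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid coordinates")
            per_chrom.setdefault(chrom, []).append([start, end, value])
    data = {}
    for chrom, recs in per_chrom.items():
        arr = np.array(recs)
        data[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    try:
        return CoverageTrack(data)
    except ValueError as exc:
        raise BedParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    return path


# ---------------------------------------------------------------------------
# peak overlap statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStats:
    """Reciprocal overlap counts and percentages between two peak sets.

    A peak "overlaps" the other set iff it shares at least ``min_overlap_bp``
    base pairs with at least one peak of that set (half-open intervals, so
    adjacent peaks share nothing). Percentages are None for an empty set.
    """

    n_a: int
    n_b: int
    n_a_hit: int
    n_b_hit: int
    min_overlap_bp: int = 1

    @property
    def pct_a_in_b(self) -> float | None:
        return 100.0 * self.n_a_hit / self.n_a if self.n_a else None

    @property
    def pct_b_in_a(self) -> float | None:
        return 100.0 * self.n_b_hit / self.n_b if self.n_b else None

    def to_frame(self, label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"set": label_a, "n_peaks": self.n_a, "n_overlapping": self.n_a_hit,
                 "pct_overlapping": self.pct_a_in_b},
                {"set": label_b, "n_peaks": self.n_b, "n_overlapping": self.n_b_hit,
                 "pct_overlapping": self.pct_b_in_a},
            ]
        )


def _count_hits(query: PeakSet, subject: PeakSet, min_overlap_bp: int) -> int:
    """Number of query peaks sharing >= min_overlap_bp with subject peaks.

    Sorted sweep: within each chromosome the subject intervals are merged and
    sorted, so the candidates overlapping query [s, e) form the contiguous
    index range [searchsorted(ends, s, right), searchsorted(starts, e, left)).
    """
    subj = subject.by_chrom()
    hits = 0
    for chrom, grp in query.intervals.groupby("chrom", sort=False):
        if chrom not in subj:
            continue
        s_starts, s_ends = subj[chrom]
        q_start = grp["start"].to_numpy()
        q_end = grp["end"].to_numpy()
        lo = np.searchsorted(s_ends, q_start, side="right")
        hi = np.searchsorted(s_starts, q_end, side="left")
        if min_overlap_bp <= 1:
            hits += int(np.count_nonzero(hi > lo))
        else:
            for qs, qe, a, b in zip(q_start, q_end, lo, hi):
                if a >= b:
                    continue
                ov = np.minimum(s_ends[a:b], qe) - np.maximum(s_starts[a:b], qs)
                if ov.max() >= min_overlap_bp:
                    hits += 1
    return hits


def overlap_stats(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> OverlapStats:
    """Reciprocal overlap statistics between two sorted peak sets."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    n_a_hit = _count_hits(a, b, min_overlap_bp)
    n_b_hit = _count_hits(b, a, min_overlap_bp)
    if len(a) == 0 or len(b) == 0:
        logger.warning("overlap_stats: empty peak set (n_a=%d, n_b=%d)", len(a), len(b))
    return OverlapStats(
        n_a=len(a), n_b=len(b), n_a_hit=n_a_hit, n_b_hit=n_b_hit,
        min_overlap_bp=min_overlap_bp,
    )


# ---------------------------------------------------------------------------
# peak-centered coverage matrices and composite profiles
# ---------------------------------------------------------------------------

@dataclass
class CoverageMatrix:
    """log2(coverage + pseudocount) in windows centered on peak midpoints.

    Rows correspond one-to-one (same order) to ``peaks``; columns are bp
    offsets from each peak midpoint, from -window_bp/2 to window_bp/2 - 1.
    """

    values: np.ndarray
    peaks: PeakSet
    window_bp: int
    pseudocount: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peaks), self.window_bp):
            raise ValueError("matrix shape does not match peaks/window")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @property
    def offsets(self) -> np.ndarray:
        half = self.window_bp // 2
        return np.arange(-half, half)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.offsets)
        df.insert(0, "chrom", self.peaks.intervals["chrom"].to_numpy())
        df.insert(1, "start", self.peaks.intervals["start"].to_numpy())
        df.insert(2, "end", self.peaks.intervals["end"].to_numpy())
        return df


def centered_matrix(
    track: CoverageTrack,
    peaks: PeakSet,
    window_bp: int = 4000,
    pseudocount: float = 1.0,
) -> CoverageMatrix:
    """Extract log2-transformed coverage in windows centered on peak midpoints.

    Each row is the coverage over ``[mid - window_bp/2, mid + window_bp/2)``
    for one peak (midpoint = floor((start + end)/2)); positions outside the
    covered chromosome extent contribute zero coverage before the transform.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be even and positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    half = window_bp // 2
    mids = peaks.midpoints
    rows = np.empty((len(peaks), window_bp))
    missing: set[str] = set()
    for i, (chrom, mid) in enumerate(zip(mids["chrom"], mids["mid"])):
        if chrom not in track.data:
            missing.add(chrom)
        rows[i] = track.window(chrom, int(mid) - half, int(mid) + half)
    for chrom in sorted(missing):
        warnings.warn(f"chromosome {chrom!r} absent from track; rows are background")
        logger.warning("chromosome %s absent from coverage track", chrom)
    return CoverageMatrix(
        values=np.log2(rows + pseudocount),
        peaks=peaks,
        window_bp=window_bp,
        pseudocount=pseudocount,
    )


def sort_rows_by_signal(m: CoverageMatrix, reference: CoverageMatrix) -> np.ndarray:
    """Row order sorting ``m`` by descending mean signal in ``reference``.

    The two matrices must be built on the identical peak list; ties keep the
    original (coordinate-sorted) order. Returns the permutation of row
    indices; apply as ``m.values[order]``.
    """
    if not m.peaks.intervals[["chrom", "start", "end"]].equals(
        reference.peaks.intervals[["chrom", "start", "end"]]
    ):
        raise ValueError("matrices are built on different peak lists")
    means = reference.values.mean(axis=1)
    return np.argsort(-means, kind="stable")


def composite_profile(m: CoverageMatrix) -> np.ndarray:
    """Column-wise mean over peaks — the composite (metagene) profile."""
    if m.values.shape[0] == 0:
        raise ValueError("cannot form a composite of an empty matrix")
    return m.values.mean(axis=0)
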