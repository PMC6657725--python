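"""Band detection on one channel of a traced line profile.

A band is a local maximum of fluorescence intensity along the trace. The
detector keeps every candidate maximum whose height reaches a fixed fraction
of the segment's own maximum intensity (background rejection, default 20%)
and then enforces a minimum distance between retained maxima (default
0.6 μm) so a single wide band is never counted twice: candidates are
accepted greedily in order of descending height, ties broken by the smaller
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import IntensityProfile

__all__ = ["BandSet", "detect_bands", "read_bands", "write_bands"]


@dataclass
class BandSet:
    """Detected bands of one channel of one segment, sorted by position."""

    channel: str
    positions: np.ndarray          # μm
    heights: np.ndarray            # intensity at the band maximum
    min_distance_um: float
    threshold_frac: float
    segment_id: str = "segment"
    larva_id: str = "larva"
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have equal length")

    def __len__(self) -> int:
        return int(self.positions.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.positions,
                "height": self.heights,
                "channel": self.channel,
                "segment_id": self.segment_id,
                "larva_id": self.larva_id,
                "condition": self.condition,
            }
        )


def _candidate_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict interior local maxima; an interior plateau that is
    higher than both flanking samples contributes its midpoint index (left
    midpoint for even plateau lengths). Trace endpoints are never maxima."""
    n = y.size
    out: list[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def detect_bands(
    profile: IntensityProfile,
    channel: str,
    min_distance_um: float = 0.6,
    threshold_frac: float = 0.20,
) -> BandSet:
    """Detect bands as thresholded, distance-separated local maxima.

    Parameters
    ----------
    profile : IntensityProfile
        The traced segment.
    channel : str
        Which channel to analyse.
    min_distance_um : float
        Minimum distance between retained maxima, in μm along the trace
        (distances use the positions axis, so resampled traces agree).
    threshold_frac : float
        Background threshold as a fraction of the channel's maximum over
        this segment; candidates below it are discarded.

    Returns
    -------
    BandSet
        Retained bands sorted by position. An all-zero channel yields an
        empty set (its relative threshold is undefined).
    """
    if channel not in profile.channels:
        raise KeyError(
            f"unknown channel {channel!r}; profile has {sorted(profile.channels)}"
        )
    if min_distance_um <= 0:
        raise ValueError("min_distance_um must be positive")
    if not 0.0 <= threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in [0, 1)")
    if profile.n_samples < 3:
        raise ValueError("profile needs at least 3 samples")
    y = profile.channels[channel]
    meta = dict(
        channel=channel,
        min_distance_um=min_distance_um,
        threshold_frac=threshold_frac,
        segment_id=profile.segment_id,
        larva_id=profile.larva_id,
        condition=profile.condition,
    )
    ymax = y.max()
    if ymax <= 0:
        return BandSet(positions=np.empty(0), heights=np.empty(0), **meta)
    threshold = threshold_frac * ymax
    cand = [i for i in _candidate_maxima(y) if y[i] >= threshold]
    # greedy min-distance pruning: descending height, ties by smaller position
    cand.sort(key=lambda i: (-y[i], profile.positions[i]))
    accepted: list[int] = []
    for i in cand:
        pos = profile.positions[i]
        if all(abs(profile.positions[j] - pos) >= min_distance_um for j in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: profile.positions[i])
    idx = np.array(accepted, dtype=int)
    return BandSet(
        positions=profile.positions[idx] if idx.size else np.empty(0),
        heights=y[idx] if idx.size else np.empty(0),
        **meta,
    )


def write_bands(bands: BandSet | list[BandSet], path: str | Path) -> Path:
    """Write one or more band sets as a delimited table with a parameter header."""
    if isinstance(bands, BandSet):
        bands = [bands]
    if not bands:
        raise ValueError("no band sets to write")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# min_distance_um={bands[0].min_distance_um}\n")
        fh.write(f"# threshold_frac={bands[0].threshold_frac}\n")
        pd.concat([b.to_frame() for b in bands], ignore_index=True).to_csv(
            fh, sep="\t", index=False, float_format="%.8g"
        )
    return path


def read_bands(path: str | Path) -> list[BandSet]:
    """Read band sets written by :func:`write_bands`, one per (segment, channel)."""
    path = Path(path)
    params: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            params[key.strip()] = float(value)
        else:
            body.append(line)
    import io

    frame = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    frame["condition"] = frame["condition"].fillna("")
    out = []
    for (segment_id, channel), grp in frame.groupby(["segment_id", "channel"], sort=True):
        out.append(
            BandSet(
                channel=channel,
                positions=grp["position_um"].to_numpy(),
                heights=grp["height"].to_numpy(),
                min_distance_um=params.get("min_distance_um", np.nan),
                threshold_frac=params.get("threshold_frac", np.nan),
                segment_id=segment_id,
                larva_id=str(grp["larva_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return out
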