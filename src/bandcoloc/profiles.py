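"""Intensity line profiles traced along polytene chromosome segments.

A profile is one traced segment: uniformly sampled positions (in μm) along
the trace, with one nonnegative intensity series per fluorescence channel
(two signal channels plus a DNA counterstain in the standard layout).
Profiles are stored as tab-delimited text, one file per segment, with
``# key=value`` header lines carrying the segment's identity.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative tolerance for the uniform-spacing check of the positions axis
SPACING_RTOL = 1e-9

#: column order of the on-disk profile format
PROFILE_COLUMNS = ("position_um", "channel_a", "channel_b", "dna")


class ProfileParseError(ValueError):
    """A profile file violates the format contract."""


@dataclass
class IntensityProfile:
    """Sampled fluorescence intensities along one traced segment.

    Parameters
    ----------
    positions : ndarray
        Sample positions in μm, strictly increasing, uniformly spaced.
    channels : dict of str -> ndarray
        Nonnegative intensity series, all sharing the positions axis.
    segment_id, larva_id, condition : str
        Identity of the measurement (which segment of which larva of which
        genotype condition).
    ground_truth : dict, optional
        For simulated profiles: ``{channel: array of true band centers}``
        plus a ``"coloc_centers"`` entry listing the co-placed centers.
    """

    positions: np.ndarray
    channels: dict[str, np.ndarray]
    segment_id: str = "segment"
    larva_id: str = "larva"
    condition: str = ""
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise ValueError("positions must be a 1-D array with >= 2 samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=SPACING_RTOL, atol=0.0):
            raise ValueError("positions must be uniformly spaced")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, series in self.channels.items():
            if series.shape != self.positions.shape:
                raise ValueError(
                    f"channel {name!r} has length {series.size}, "
                    f"expected {self.positions.size}"
                )
            if np.any(series < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def sampling_step(self) -> float:
        """Spacing of the positions axis in μm."""
        return float(self.positions[1] - self.positions[0])

    @property
    def n_samples(self) -> int:
        return int(self.positions.size)

    def to_frame(self) -> pd.DataFrame:
        data = {"position_um": self.positions}
        data.update(self.channels)
        return pd.DataFrame(data)


def write_profile(profile: IntensityProfile, path: str | Path) -> Path:
    """Write one profile as tab-delimited text with identity header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# segment_id={profile.segment_id}\n")
        fh.write(f"# larva_id={profile.larva_id}\n")
        fh.write(f"# condition={profile.condition}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")
    return path


def write_ground_truth(profile: IntensityProfile, path: str | Path) -> Path:
    """Write the simulated band centers of a profile as a sidecar table."""
    if profile.ground_truth is None:
        raise ValueError("profile carries no ground truth")
    rows = []
    coloc = set(np.round(profile.ground_truth.get("coloc_centers", []), 9))
    for channel, centers in profile.ground_truth.items():
        if channel == "coloc_centers":
            continue
        for c in centers:
            rows.append(
                {
                    "channel": channel,
                    "center_um": c,
                    "co_placed": int(round(c, 9) in coloc),
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=["channel", "center_um", "co_placed"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def _read_one(path: Path) -> IntensityProfile | None:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    n_fields: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if "=" in text:
                    key, _, value = text.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if n_fields is None:
                n_fields = len(fields)
            elif len(fields) != n_fields:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected {n_fields} columns, got {len(fields)}"
                )
            body_lines.append(line)
    if not body_lines:
        warnings.warn(f"profile file {path} is empty; skipping", stacklevel=3)
        logger.warning("profile file %s is empty; skipping", path)
        return None
    try:
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ProfileParseError(f"{path}: cannot parse table: {exc}") from exc
    if "position_um" not in frame.columns:
        raise ProfileParseError(f"{path}: missing required column 'position_um'")
    positions = frame["position_um"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(positions) <= 0)[0]
    if bad.size:
        # +2 header line, +1 0-based, +1 second element of the failing pair
        lineno = int(bad[0]) + 3 + len(meta)
        raise ProfileParseError(
            f"{path}:{lineno}: positions are not strictly increasing"
        )
    channels = {
        c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "position_um"
    }
    try:
        return IntensityProfile(
            positions=positions,
            channels=channels,
            segment_id=meta.get("segment_id", path.stem),
            larva_id=meta.get("larva_id", "larva"),
            condition=meta.get("condition", ""),
        )
    except ValueError as exc:
        raise ProfileParseError(f"{path}: {exc}") from exc


def read_profiles(path: str | Path) -> list[IntensityProfile]:
    """Read profiles from one file or every ``*.tsv`` file in a directory.

    Empty files yield a warning and are skipped; structurally broken files
    raise :class:`ProfileParseError` naming the offending line.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.glob("*.tsv")
            if not p.name.endswith((".bands.tsv", ".truth.tsv", ".segments.tsv"))
        )
    else:
        files = [path]
    profiles = []
    for f in files:
        profile = _read_one(f)
        if profile is not None:
            profiles.append(profile)
    return profiles
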