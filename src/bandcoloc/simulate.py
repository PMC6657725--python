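"""Synthetic line profiles and genomic track pairs with known ground truth.

The profile generator emulates the signal structure of two-channel
immunofluorescence traces along polytene chromosome segments: discrete
Gaussian-shaped bands over a constant background, with a controllable
fraction of channel-B bands placed exactly at channel-A band centers, plus
zero-truncated Gaussian noise and a smooth DNA-counterstain envelope. The
track generator produces paired BED/bedGraph-style peak sets and coverage
tracks with a planted overlap fraction. Both report their ground truth so
every downstream estimator can be checked against planted values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genomic import CoverageTrack, PeakSet
from .profiles import IntensityProfile

__all__ = [
    "PackingError",
    "ProfileSimConfig",
    "TrackSimConfig",
    "simulate_profile",
    "simulate_condition",
    "simulate_tracks",
]

#: rejection-sampling attempts per band before declaring the packing infeasible
_MAX_ATTEMPTS_PER_BAND = 2000


class PackingError(RuntimeError):
    """Requested bands/peaks cannot be packed at the required spacing."""


@dataclass(frozen=True)
class ProfileSimConfig:
    """Parameters of one simulated two-channel line profile.

    Defaults describe a 60 μm traced segment sampled every 0.05 μm with ten
    well-separated bands per channel over a dim background — a trace a
    scorer would accept (clearly separable bands, at least one prominent
    band per channel). Band amplitudes span faint-to-bright (faint bands
    near background are why the relative detection threshold exists, and
    their stochastic loss is the measurement variability of real scoring).
    ``min_band_spacing`` applies within each channel and between
    non-co-placed bands of different channels, so the planted
    ``coloc_fraction`` is the true fraction of co-occurring bands.
    """

    segment_length: float = 60.0          # μm
    sampling_step: float = 0.05           # μm
    n_bands_a: int = 10
    n_bands_b: int = 10
    coloc_fraction: float = 0.5
    band_sigma: float = 0.2               # μm
    amplitude_range: tuple[float, float] = (5.0, 120.0)
    background_level: float = 10.0
    noise_sd: float = 2.0
    min_band_spacing: float = 1.2         # μm
    center_jitter: float = 0.0            # μm, sd of jitter on co-placed B centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_length <= 0 or self.sampling_step <= 0:
            raise ValueError("segment_length and sampling_step must be positive")
        if self.sampling_step >= self.band_sigma:
            raise ValueError("sampling_step must be smaller than band_sigma")
        if self.n_bands_a < 0 or self.n_bands_b < 0:
            raise ValueError("band counts must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("amplitude_range must be positive and ordered")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if self.min_band_spacing <= 0:
            raise ValueError("min_band_spacing must be positive")
        if self.center_jitter < 0:
            raise ValueError("center_jitter must be >= 0")

    @property
    def n_coloc(self) -> int:
        """Planted number of B bands co-placed with A bands (round half up)."""
        return int(np.floor(self.coloc_fraction * self.n_bands_b + 0.5))


def _place_centers(
    rng: np.random.Generator,
    n: int,
    low: float,
    high: float,
    spacing: float,
    avoid: np.ndarray,
) -> np.ndarray:
    """Rejection-sample n centers in [low, high], pairwise and vs avoid >= spacing."""
    centers: list[float] = []
    budget = _MAX_ATTEMPTS_PER_BAND * max(n, 1)
    while len(centers) < n:
        if budget <= 0:
            raise PackingError(
                f"could not place {n} band centers at spacing {spacing} "
                f"in [{low:.3g}, {high:.3g}] — packing infeasible"
            )
        budget -= 1
        c = rng.uniform(low, high)
        taken = np.concatenate([avoid, np.array(centers)])
        if taken.size == 0 or np.abs(taken - c).min() >= spacing:
            centers.append(c)
    return np.array(centers)


def simulate_profile(
    config: ProfileSimConfig,
    segment_id: str = "segment",
    larva_id: str = "larva",
    condition: str = "",
    rng: np.random.Generator | None = None,
) -> IntensityProfile:
    """Simulate one two-channel profile with ground-truth band centers.

    Raises :class:`PackingError` when the requested number of bands cannot
    fit in the segment at ``min_band_spacing`` (explicit failure, never
    silent truncation).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    margin = 4.0 * config.band_sigma
    low, high = margin, config.segment_length - margin
    if high <= low:
        raise PackingError("segment too short for the band width margin")
    n_coloc = config.n_coloc
    if n_coloc > config.n_bands_a:
        raise PackingError(
            f"coloc_fraction requires {n_coloc} co-placed B bands but only "
            f"{config.n_bands_a} A bands exist"
        )
    # necessary condition before sampling: all distinct sites fit at spacing
    n_sites = config.n_bands_a + (config.n_bands_b - n_coloc)
    if n_sites > 0 and (n_sites - 1) * config.min_band_spacing > (high - low):
        raise PackingError(
            f"{n_sites} distinct band sites at spacing {config.min_band_spacing} μm "
            f"do not fit in the usable {high - low:.3g} μm"
        )

    centers_a = _place_centers(
        rng, config.n_bands_a, low, high, config.min_band_spacing, np.empty(0)
    )
    coloc_idx = rng.choice(config.n_bands_a, size=n_coloc, replace=False) if n_coloc else []
    centers_b_coloc = centers_a[coloc_idx].copy() if n_coloc else np.empty(0)
    if config.center_jitter > 0 and n_coloc:
        centers_b_coloc = centers_b_coloc + rng.normal(0, config.center_jitter, n_coloc)
    # free B bands avoid all A centers too, so chance co-occurrence is excluded
    centers_b_free = _place_centers(
        rng,
        config.n_bands_b - n_coloc,
        low,
        high,
        config.min_band_spacing,
        np.concatenate([centers_a, centers_b_coloc]),
    )
    centers_b = np.concatenate([centers_b_coloc, centers_b_free])

    positions = np.arange(0.0, config.segment_length + 0.5 * config.sampling_step,
                          config.sampling_step)

    def render(centers: np.ndarray) -> np.ndarray:
        y = np.full(positions.size, config.background_level, dtype=float)
        amps = rng.uniform(*config.amplitude_range, size=centers.size)
        halfwin = 6.0 * config.band_sigma
        for c, a in zip(centers, amps):
            i0 = int(np.searchsorted(positions, c - halfwin))
            i1 = int(np.searchsorted(positions, c + halfwin))
            x = positions[i0:i1]
            y[i0:i1] += a * np.exp(-0.5 * ((x - c) / config.band_sigma) ** 2)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, y.size)
        return np.maximum(y, 0.0)

    channel_a = render(centers_a)
    channel_b = render(centers_b)
    # smooth positive DNA-counterstain envelope; carries no band information
    dna = 100.0 * (1.0 + 0.25 * np.sin(2.0 * np.pi * positions / config.segment_length * 3.0))

    ground_truth = {
        "channel_a": np.sort(centers_a),
        "channel_b": np.sort(centers_b),
        "coloc_centers": np.sort(centers_b_coloc),
    }
    return IntensityProfile(
        positions=positions,
        channels={"channel_a": channel_a, "channel_b": channel_b, "dna": dna},
        segment_id=segment_id,
        larva_id=larva_id,
        condition=condition,
        ground_truth=ground_truth,
    )


def simulate_condition(
    config: ProfileSimConfig,
    n_larvae: int = 6,
    segments_per_larva: int = 3,
    condition: str = "condition",
    seed: int | None = None,
) -> dict[str, list[IntensityProfile]]:
    """Simulate a grouped condition: ``n_larvae`` larvae × segments each.

    Per-segment generators are spawned deterministically from the master
    seed, so the same seed reproduces the whole condition bitwise.
    """
    if n_larvae < 1 or segments_per_larva < 1:
        raise ValueError("need at least one larva and one segment per larva")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    children = master.spawn(n_larvae * segments_per_larva)
    out: dict[str, list[IntensityProfile]] = {}
    k = 0
    for i in range(n_larvae):
        larva_id = f"{condition}_larva{i + 1}"
        out[larva_id] = []
        for j in range(segments_per_larva):
            rng = np.random.default_rng(children[k])
            k += 1
            out[larva_id].append(
                simulate_profile(
                    config,
                    segment_id=f"{larva_id}_seg{j + 1}",
                    larva_id=larva_id,
                    condition=condition,
                    rng=rng,
                )
            )
    return out


# ---------------------------------------------------------------------------
# genomic track simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters of a paired peak/coverage simulation with planted overlap.

    ``overlap_fraction`` of the B peaks are co-centered on distinct A peaks
    (guaranteed >= 1 bp shared); the rest are placed sharing no base pair
    with A. Coverage is ``coverage_enrichment`` times the unit background
    over each peak of the matching set.
    """

    genome: tuple[tuple[str, int], ...] = (("chr2L", 200_000), ("chr2R", 200_000))
    n_peaks_a: int = 60
    n_peaks_b: int = 60
    overlap_fraction: float = 0.5
    peak_width_bp: int = 400
    coverage_enrichment: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.n_peaks_a < 0 or self.n_peaks_b < 0:
            raise ValueError("peak counts must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.peak_width_bp <= 0:
            raise ValueError("peak_width_bp must be positive")
        if self.coverage_enrichment <= 0:
            raise ValueError("coverage_enrichment must be positive")

    @property
    def n_overlap(self) -> int:
        """Planted number of B peaks overlapping A (round half up)."""
        return int(np.floor(self.overlap_fraction * self.n_peaks_b + 0.5))


def _sample_peak(
    rng: np.random.Generator,
    genome: tuple[tuple[str, int], ...],
    width: int,
    occupied: dict[str, list[tuple[int, int]]],
) -> tuple[str, int, int]:
    names = [c for c, _ in genome]
    lengths = np.array([ln for _, ln in genome], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(_MAX_ATTEMPTS_PER_BAND):
        chrom = names[rng.choice(len(names), p=weights)]
        length = dict(genome)[chrom]
        if length <= width:
            continue
        start = int(rng.integers(0, length - width))
        end = start + width
        if all(end <= s or start >= e for s, e in occupied.get(chrom, [])):
            return chrom, start, end
    raise PackingError("could not place a peak without forbidden overlap")


def simulate_tracks(
    config: TrackSimConfig,
) -> tuple[PeakSet, PeakSet, CoverageTrack, CoverageTrack]:
    """Simulate paired peak sets and coverage tracks with planted overlap."""
    rng = np.random.default_rng(config.seed)
    n_overlap = config.n_overlap
    if n_overlap > config.n_peaks_a:
        raise PackingError(
            f"overlap_fraction requires {n_overlap} overlapping B peaks "
            f"but only {config.n_peaks_a} A peaks exist"
        )

    occupied_a: dict[str, list[tuple[int, int]]] = {}
    peaks_a: list[tuple[str, int, int]] = []
    for _ in range(config.n_peaks_a):
        chrom, s, e = _sample_peak(rng, config.genome, config.peak_width_bp, occupied_a)
        occupied_a.setdefault(chrom, []).append((s, e))
        peaks_a.append((chrom, s, e))

    anchor_idx = rng.choice(config.n_peaks_a, size=n_overlap, replace=False) if n_overlap else []
    peaks_b: list[tuple[str, int, int]] = [peaks_a[i] for i in anchor_idx]
    # non-overlapping B peaks must avoid every A peak and every placed B peak
    occupied_b: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in peaks_a + peaks_b:
        occupied_b.setdefault(chrom, []).append((s, e))
    for _ in range(config.n_peaks_b - n_overlap):
        chrom, s, e = _sample_peak(rng, config.genome, config.peak_width_bp, occupied_b)
        occupied_b.setdefault(chrom, []).append((s, e))
        peaks_b.append((chrom, s, e))

    def to_set(peaks: list[tuple[str, int, int]], label: str) -> PeakSet:
        frame = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
        return PeakSet(frame, label=label)

    set_a = to_set(peaks_a, "A")
    set_b = to_set(peaks_b[: len(peaks_b)], "B")

    def to_track(peaks: PeakSet) -> CoverageTrack:
        data = {}
        by_chrom = peaks.by_chrom()
        for chrom, length in config.genome:
            starts, ends, values = [], [], []
            pos = 0
            p_starts, p_ends = by_chrom.get(chrom, (np.empty(0, int), np.empty(0, int)))
            for ps, pe in zip(p_starts, p_ends):
                if ps > pos:
                    starts.append(pos); ends.append(ps); values.append(1.0)
                starts.append(ps); ends.append(pe); values.append(config.coverage_enrichment)
                pos = pe
            if pos < length:
                starts.append(pos); ends.append(length); values.append(1.0)
            data[chrom] = (np.array(starts), np.array(ends), np.array(values))
        return CoverageTrack(data)

    return set_a, set_b, to_track(set_a), to_track(set_b)


def with_coloc_fraction(config: ProfileSimConfig, rho: float, seed: int) -> ProfileSimConfig:
    """Convenience: the same profile conditions at a different planted ρ."""
    return replace(config, coloc_fraction=rho, seed=seed)
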