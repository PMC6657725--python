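"""Simulation studies: calibration, recovery and power of the pipeline.

These run the full quantification chain (simulate profiles → detect bands →
match → aggregate per larva → permutation test) under known ground truth,
and are what the ``calibrate`` pipeline stage and the verification suite
execute.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .coloc import ConditionData, coloc_percent, permutation_test, summarize_larvae
from .detect import detect_bands
from .simulate import ProfileSimConfig, simulate_condition

__all__ = [
    "quantify_condition",
    "type1_error_study",
    "recovery_study",
    "power_study",
]


def quantify_condition(
    profiles_by_larva: dict,
    min_distance_um: float = 0.6,
    threshold_frac: float = 0.20,
    tolerance_um: float = 0.6,
    condition: str | None = None,
) -> ConditionData:
    """Detect bands on both channels and aggregate colocalization per larva."""
    segments = []
    for profiles in profiles_by_larva.values():
        for p in profiles:
            ba = detect_bands(p, "channel_a", min_distance_um, threshold_frac)
            bb = detect_bands(p, "channel_b", min_distance_um, threshold_frac)
            segments.append(coloc_percent(ba, bb, tolerance_um=tolerance_um))
    return summarize_larvae(segments, condition=condition or segments[0].condition)


def type1_error_study(
    n_replicates: int = 2000,
    n_per_group: int = 6,
    n_permutations: int = 999,
    alpha: float = 0.05,
    mean: float = 50.0,
    sd: float = 10.0,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate when both conditions share one distribution.

    Both groups are drawn i.i.d. normal (percent-like location and spread);
    a correctly calibrated test rejects at level ``alpha`` no more often
    than ``alpha`` up to the discreteness of the permutation null.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(mean, sd, n_per_group)
        b = rng.normal(mean, sd, n_per_group)
        res = permutation_test(
            a, b, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        rejections += res.p_value <= alpha
    return {
        "n_replicates": n_replicates,
        "n_rejections": rejections,
        "rejection_rate": rejections / n_replicates,
        "alpha": alpha,
    }


def recovery_study(
    rho_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    base_config: ProfileSimConfig | None = None,
    n_larvae: int = 6,
    segments_per_larva: int = 3,
    seed: int = 0,
    tolerance_um: float = 0.6,
) -> pd.DataFrame:
    """Recovered mean colocalization percent across planted fractions ρ.

    Returns one row per ρ with the pipeline's estimate and its error
    against the planted 100ρ.
    """
    if base_config is None:
        base_config = ProfileSimConfig()
    rows = []
    for k, rho in enumerate(rho_grid):
        config = replace(base_config, coloc_fraction=float(rho), seed=seed + 1000 + k)
        grouped = simulate_condition(
            config, n_larvae=n_larvae, segments_per_larva=segments_per_larva,
            condition=f"rho={rho}",
        )
        data = quantify_condition(grouped, tolerance_um=tolerance_um)
        rows.append(
            {
                "rho": float(rho),
                "planted_percent": 100.0 * float(rho),
                "recovered_percent": data.mean,
                "abs_error_pp": abs(data.mean - 100.0 * float(rho)),
                "n_larvae": data.n_larvae,
            }
        )
    return pd.DataFrame(rows)


def power_study(
    rho_a: float = 0.9,
    rho_b: float = 0.2,
    n_replicates: int = 200,
    n_larvae: int = 6,
    segments_per_larva: int = 3,
    n_permutations: int = 999,
    base_config: ProfileSimConfig | None = None,
    seed: int = 0,
    tolerance_um: float = 0.6,
) -> np.ndarray:
    """Permutation p-values comparing two planted colocalization fractions.

    With ``rho_a != rho_b`` this measures power; with equal fractions the
    p-values should be (conservatively) uniform. Returns the replicate
    p-values.
    """
    if base_config is None:
        base_config = ProfileSimConfig()
    master = np.random.SeedSequence(seed)
    p_values = np.empty(n_replicates)
    for r, child in enumerate(master.spawn(n_replicates)):
        s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in child.spawn(3))
        cond_a = simulate_condition(
            replace(base_config, coloc_fraction=rho_a, seed=s1),
            n_larvae=n_larvae, segments_per_larva=segments_per_larva, condition="a",
        )
        cond_b = simulate_condition(
            replace(base_config, coloc_fraction=rho_b, seed=s2),
            n_larvae=n_larvae, segments_per_larva=segments_per_larva, condition="b",
        )
        res = permutation_test(
            quantify_condition(cond_a, tolerance_um=tolerance_um),
            quantify_condition(cond_b, tolerance_um=tolerance_um),
            n_permutations=n_permutations,
            seed=s3,
        )
        p_values[r] = res.p_value
    return p_values
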