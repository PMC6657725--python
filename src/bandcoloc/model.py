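"""Model/results interface for comparing colocalization across conditions.

``ColocalizationModel`` holds per-larva mean colocalization percentages
grouped by genotype condition, with one condition designated the control.
``fit`` runs a permutation test of each non-control condition against the
control and returns a ``ColocalizationResults`` object carrying the
estimates, the permutation null summaries and a ``summary()`` table, in the
style of statsmodels model/results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import (
    ConditionData,
    PermutationResult,
    SegmentColoc,
    coloc_percent,
    permutation_test,
    summarize_larvae,
)
from .detect import detect_bands
from .profiles import IntensityProfile


class ColocalizationModel:
    """Band-colocalization comparison of genotype conditions to a control.

    Parameters
    ----------
    data : DataFrame
        Per-larva data with columns ``condition``, ``larva_id``, ``percent``
        (each larva appears once; percent is that larva's mean over its
        segments).
    control : str
        The condition every other condition is tested against.
    """

    def __init__(self, data: pd.DataFrame, control: str):
        required = {"condition", "larva_id", "percent"}
        if not required.issubset(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        if data.duplicated(["condition", "larva_id"]).any():
            raise ValueError("each larva must appear once per condition")
        if control not in set(data["condition"]):
            raise ValueError(f"control condition {control!r} not present in data")
        if ((data["percent"] < 0) | (data["percent"] > 100)).any():
            raise ValueError("percent values must lie in [0, 100]")
        self.data = data.reset_index(drop=True)
        self.control = control

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_conditions(
        cls, conditions: list[ConditionData], control: str
    ) -> "ColocalizationModel":
        rows = [
            {"condition": c.condition, "larva_id": larva, "percent": value}
            for c in conditions
            for larva, value in c.larva_means.items()
        ]
        return cls(pd.DataFrame(rows), control=control)

    @classmethod
    def from_segments(
        cls, segments: list[SegmentColoc], control: str
    ) -> "ColocalizationModel":
        by_condition: dict[str, list[SegmentColoc]] = {}
        for s in segments:
            by_condition.setdefault(s.condition, []).append(s)
        conditions = [
            summarize_larvae(group, condition=cond)
            for cond, group in by_condition.items()
        ]
        return cls.from_conditions(conditions, control=control)

    @classmethod
    def from_profiles(
        cls,
        profiles: list[IntensityProfile],
        control: str,
        channel_a: str = "channel_a",
        channel_b: str = "channel_b",
        min_distance_um: float = 0.6,
        threshold_frac: float = 0.20,
        tolerance_um: float = 0.6,
    ) -> "ColocalizationModel":
        """Run the full quantification (detection, matching, aggregation)."""
        segments = []
        for p in profiles:
            ba = detect_bands(p, channel_a, min_distance_um, threshold_frac)
            bb = detect_bands(p, channel_b, min_distance_um, threshold_frac)
            segments.append(coloc_percent(ba, bb, tolerance_um=tolerance_um))
        return cls.from_segments(segments, control=control)

    # -- inference ----------------------------------------------------------

    def condition_data(self, condition: str) -> ConditionData:
        sub = self.data[self.data["condition"] == condition]
        return ConditionData(
            condition=condition,
            larva_means=pd.Series(
                sub["percent"].to_numpy(), index=sub["larva_id"].to_numpy()
            ),
        )

    @property
    def conditions(self) -> list[str]:
        ordered = list(dict.fromkeys(self.data["condition"]))
        return [self.control] + [c for c in ordered if c != self.control]

    def fit(
        self, n_permutations: int = 100_000, seed: int | None = None
    ) -> "ColocalizationResults":
        """Permutation-test every non-control condition against the control."""
        control_data = self.condition_data(self.control)
        tests = {}
        for cond in self.conditions[1:]:
            tests[cond] = permutation_test(
                self.condition_data(cond),
                control_data,
                n_permutations=n_permutations,
                seed=seed,
            )
        return ColocalizationResults(model=self, tests=tests, seed=seed)


@dataclass
class ColocalizationResults:
    """Fitted condition comparison: estimates, permutation tests, summary."""

    model: ColocalizationModel
    tests: dict[str, PermutationResult]
    seed: int | None = None

    @property
    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.model.conditions:
            data = self.model.condition_data(cond)
            test = self.tests.get(cond)
            rows.append(
                {
                    "condition": cond,
                    "n_larvae": data.n_larvae,
                    "mean_percent": data.mean,
                    "sd_percent": float(np.std(data.values, ddof=1))
                    if data.n_larvae > 1
                    else float("nan"),
                    "diff_vs_control": test.observed_diff if test else 0.0,
                    "p_value": test.p_value if test else float("nan"),
                    "test_mode": test.mode if test else "control",
                }
            )
        return pd.DataFrame(rows)

    def p_value(self, condition: str) -> float:
        return self.tests[condition].p_value

    def summary(self) -> str:
        """Human-readable summary table of the fitted comparison."""
        frame = self.summary_frame.copy()
        frame["mean_percent"] = frame["mean_percent"].map("{:.2f}".format)
        frame["sd_percent"] = frame["sd_percent"].map("{:.2f}".format)
        frame["diff_vs_control"] = frame["diff_vs_control"].map("{:+.2f}".format)
        frame["p_value"] = frame["p_value"].map("{:.5g}".format)
        lines = [
            "Band colocalization — permutation comparison to control",
            f"control: {self.model.control}"
            + (f"    seed: {self.seed}" if self.seed is not None else ""),
            frame.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of condition means with per-larva points overlaid."""
        from .plotting import plot_condition_means

        return plot_condition_means(
            [self.model.condition_data(c) for c in self.model.conditions], ax=ax
        )
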