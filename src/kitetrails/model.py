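"""Model/Results interface tying the analysis pipeline together.

`MovementModel` holds one bird's trajectory plus the analysis settings;
`fit()` runs excursion classification, the with/without-excursion kernel
home ranges and the weekly behaviour cascade, returning a
:class:`MovementResults` that carries labels, ranges, week summaries and a
printable summary table. The underlying building blocks live in
:mod:`kitetrails.classifier`, :mod:`kitetrails.home_range` and
:mod:`kitetrails.behavior` and remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, geometry, home_range
from .behavior import BehaviorConfig
from .classifier import ClassifierConfig, classify, excursion_summary
from .home_range import KernelConfig
from .telemetry_io import Trajectory, trajectory_from_frame


class MovementModel:
    """Excursion/home-range/weekly-behaviour analysis of one trajectory.

    Parameters
    ----------
    trajectory : Trajectory
        One bird's time-sorted fixes (first fix at the nest).
    classifier_config, kernel_config, behavior_config : optional
        Threshold settings; defaults are the standard heuristics (30 km
        nest buffer, |v_r| > 5 km/h with |v_theta| < 45 deg/h, 3 km
        novelty, gap relabelling up to 3 fixes; 90x90 grid, 0.04 smoothing,
        90 % isopleth).

    Examples
    --------
    >>> from kitetrails import synthetic, MovementModel
    >>> traj, truth = synthetic.simulate(synthetic.benchmark_config(), seed=1)
    >>> res = MovementModel(traj).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        trajectory: Trajectory,
        classifier_config: ClassifierConfig | None = None,
        kernel_config: KernelConfig | None = None,
        behavior_config: BehaviorConfig | None = None,
    ):
        self.trajectory = trajectory
        self.classifier_config = classifier_config or ClassifierConfig()
        self.kernel_config = kernel_config or KernelConfig()
        self.behavior_config = behavior_config or BehaviorConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bird_id=None, **kwargs) -> "MovementModel":
        """Build a model from a bird_id/timestamp/lat/lon DataFrame."""
        return cls(trajectory_from_frame(df, bird_id=bird_id), **kwargs)

    def fit(self) -> "MovementResults":
        """Run the full analysis and return the results object."""
        traj = self.trajectory
        labels, rules = classify(traj, self.classifier_config)
        track = geometry.project(traj)

        settled = labels == "settlement"
        if settled.sum() >= 2:
            comparison = home_range.compare_ranges(traj, labels, self.kernel_config)
        else:
            comparison = None

        windows = behavior.assign_weeks(traj.times, self.behavior_config.week_anchor)
        ranges = home_range.weekly_ranges(traj, labels, self.kernel_config, windows)
        distances = behavior.weekly_distances(traj, windows)
        weeks = []
        for i, (window, dist) in enumerate(zip(windows, distances)):
            start, end = window
            mask = np.asarray((traj.times >= start) & (traj.times < end))
            known = ranges[i - 1] if i >= 1 else None
            weeks.append(
                behavior.classify_week(
                    traj.bird_id,
                    window,
                    track.xy[mask],
                    traj.times[mask],
                    labels[mask],
                    known,
                    dist,
                    self.behavior_config,
                )
            )
        return MovementResults(
            model=self,
            labels=labels,
            rules=rules,
            projected=track,
            comparison=comparison,
            weekly_range_list=ranges,
            weeks=weeks,
        )


@dataclass
class MovementResults:
    """Fitted movement analysis: labels, home ranges, weekly summaries."""

    model: MovementModel
    labels: np.ndarray
    rules: np.ndarray
    projected: "geometry.ProjectedTrack"
    comparison: dict | None
    weekly_range_list: list
    weeks: list = field(default_factory=list)

    # -- convenience accessors -----------------------------------------
    @property
    def trajectory(self) -> Trajectory:
        return self.model.trajectory

    @property
    def n_fixes(self) -> int:
        return len(self.labels)

    @property
    def n_excursion(self) -> int:
        return int(np.sum(self.labels == "excursion"))

    @property
    def home_range_all(self):
        return self.comparison["hr_all"] if self.comparison else None

    @property
    def home_range_settlement(self):
        return self.comparison["hr_settlement"] if self.comparison else None

    @property
    def area_ratio(self):
        return self.comparison["area_ratio"] if self.comparison else None

    def weekly_frame(self) -> pd.DataFrame:
        """Week summaries as a DataFrame."""
        return pd.DataFrame(
            [
                {
                    "bird_id": w.bird_id,
                    "week_start": w.start,
                    "week_end": w.end,
                    "n_fixes": w.n_fixes,
                    "distance_km": w.distance_km,
                    "distance_miles": w.distance_miles,
                    "pattern": w.pattern,
                    "start_range_id": w.start_range_id,
                    "end_range_id": w.end_range_id,
                }
                for w in self.weeks
            ]
        )

    def week_texts(self) -> list[str]:
        """Deterministic one-line narrative per week."""
        return [behavior.render_summary(w) for w in self.weeks]

    def summary(self) -> str:
        """Printable overview of the fitted analysis."""
        traj = self.trajectory
        lines = []
        w = 68
        lines.append("Movement analysis".center(w))
        lines.append("=" * w)
        lines.append(f"Bird id:            {traj.bird_id}")
        lines.append(f"Period:             {traj.times[0].date()} .. {traj.times[-1].date()}")
        lines.append(f"Fixes:              {self.n_fixes}")
        pct = 100.0 * self.n_excursion / self.n_fixes if self.n_fixes else 0.0
        lines.append(f"Excursion fixes:    {self.n_excursion} ({pct:.1f} %)")
        for rule in ("velocity", "novelty", "gapfill"):
            lines.append(f"  by {rule + ' rule:':<16}{int(np.sum(self.rules == rule))}")
        if self.comparison:
            hr_a = self.comparison["hr_all"]
            hr_s = self.comparison["hr_settlement"]
            lines.append("-" * w)
            lines.append(
                f"Home range ({hr_a.isopleth_level:.0%} isopleth), all fixes:      "
                f"{hr_a.area_km2:9.1f} km2 in {hr_a.n_parts} part(s)"
            )
            lines.append(
                f"Home range ({hr_s.isopleth_level:.0%} isopleth), settlement only:"
                f"{hr_s.area_km2:9.1f} km2 in {hr_s.n_parts} part(s)"
            )
            lines.append(f"Area ratio (settlement / all):   {self.comparison['area_ratio']:.3f}")
        if self.weeks:
            counts = pd.Series([wk.pattern for wk in self.weeks]).value_counts()
            lines.append("-" * w)
            lines.append("Weeks by movement pattern:")
            for pattern, count in counts.items():
                lines.append(f"  {pattern:<28}{count}")
            total_km = sum(wk.distance_km for wk in self.weeks)
            lines.append(
                f"Total distance:     {total_km:.0f} km "
                f"({geometry.km_to_miles(total_km):.0f} miles)"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def excursion_table(self) -> pd.DataFrame:
        return excursion_summary([(self.trajectory.bird_id, self.labels)])

    def plot(self, ax=None):
        """Fixes coloured by label with home-range outlines (km frame)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        xy = self.projected.xy
        exc = self.labels == "excursion"
        ax.plot(xy[~exc, 0], xy[~exc, 1], "+", color="orange", ms=5, label="settlement")
        ax.plot(xy[exc, 0], xy[exc, 1], "+", color="black", ms=5, label="excursion")
        if self.comparison:
            for poly in self.comparison["hr_all"].polygon_list:
                ax.plot(*poly.exterior.xy, color="grey", lw=1, ls="--")
            for poly in self.comparison["hr_settlement"].polygon_list:
                ax.plot(*poly.exterior.xy, color="firebrick", lw=1.5)
        ax.set_xlabel("km east of nest")
        ax.set_ylabel("km north of nest")
        ax.set_aspect("equal")
        ax.legend(loc="best", fontsize=8)
        return ax
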