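"""Reference-chart construction, centile coverage, and rendering.

A reference chart is a fan of centile curves — flexion (degrees) against
days post-surgery — evaluated on an integer day grid.  Centile coverage of
a dataset is, per level, the fraction of observations falling *strictly
below* the centile curve at the observation's own day; exact ties count as
not below (a fixed convention — ties have probability zero under the
continuous models).  A calibrated chart captures 5% of the data below the
5th centile, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ChartError

#: the chart's centile levels
DEFAULT_LEVELS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)
#: integer day grid spanning the study's observation window
DEFAULT_GRID = np.arange(2, 121)


def _level_label(level):
    return f"c{round(level * 100):02d}"


@dataclass
class ReferenceChart:
    """Time-grid x centile-level matrix of flexion values."""

    days: np.ndarray
    levels: tuple
    values: np.ndarray  # shape (len(days), len(levels))

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.days), len(self.levels)):
            raise ChartError("chart value matrix shape mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ChartError("chart values must be finite and positive")
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ChartError("centile curves must be strictly increasing in level")

    def to_frame(self):
        frame = pd.DataFrame(self.values, columns=[_level_label(l) for l in self.levels])
        frame.insert(0, "day", self.days)
        return frame

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path):
        frame = pd.read_csv(path)
        level_cols = [c for c in frame.columns if c.startswith("c")]
        levels = tuple(int(c[1:]) / 100.0 for c in level_cols)
        return cls(frame["day"].to_numpy(), levels, frame[level_cols].to_numpy())

    def interpolate(self, day):
        """Linear interpolation of every centile curve at arbitrary day(s)."""
        day = np.atleast_1d(np.asarray(day, dtype=float))
        out = np.empty((len(day), len(self.levels)))
        for j in range(len(self.levels)):
            out[:, j] = np.interp(day, self.days, self.values[:, j])
        return out


def build_chart(model, days=None, levels=DEFAULT_LEVELS):
    """Evaluate a model's centiles on a day grid.

    ``model`` is anything with a ``centile(day, alpha)`` method (a fitted
    model or the synthetic ground truth).  Raises :class:`ChartError` if
    the resulting curves are not strictly increasing across levels —
    pathological parameter curves are surfaced, never silently reordered.
    """
    days = DEFAULT_GRID if days is None else np.asarray(days, dtype=float)
    levels = tuple(float(l) for l in levels)
    if any(not 0 < l < 1 for l in levels) or list(levels) != sorted(levels):
        raise ChartError("levels must be sorted probabilities in (0, 1)")
    values = np.column_stack([np.atleast_1d(model.centile(days, l)) for l in levels])
    return ReferenceChart(days=days, levels=levels, values=values)


@dataclass
class CoverageReport:
    """Observed vs nominal proportion below each centile curve."""

    table: pd.DataFrame  # columns: level, expected_pct, observed_pct, n_below, n
    n_used: int
    n_excluded: int

    @property
    def coverage_error(self):
        """Mean absolute deviation from nominal coverage, percentage points."""
        t = self.table
        return float(np.mean(np.abs(t["observed_pct"] - t["expected_pct"])))


def coverage(model_or_chart, data, levels=None):
    """Centile coverage of a dataset against a model or chart.

    With a model, centiles are evaluated at each record's exact day; with a
    chart, curves are linearly interpolated on the day grid and records
    outside the grid are excluded (and counted in the report).
    """
    frame = data.frame if hasattr(data, "frame") else data
    day = np.asarray(frame["day_post_op"], dtype=float)
    y = np.asarray(frame["flexion_deg"], dtype=float)

    if isinstance(model_or_chart, ReferenceChart):
        chart = model_or_chart
        lv = chart.levels if levels is None else tuple(levels)
        if levels is not None and tuple(levels) != chart.levels:
            raise ChartError("levels must match the chart's levels")
        inside = (day >= chart.days[0]) & (day <= chart.days[-1])
        curves = chart.interpolate(day[inside])
        y_used = y[inside]
        n_excluded = int((~inside).sum())
    else:
        lv = DEFAULT_LEVELS if levels is None else tuple(levels)
        curves = np.column_stack(
            [np.atleast_1d(model_or_chart.centile(day, l)) for l in lv]
        )
        y_used = y
        n_excluded = 0

    n = len(y_used)
    rows = []
    for j, level in enumerate(lv):
        n_below = int(np.sum(y_used < curves[:, j])) if n else 0
        obs = 100.0 * n_below / n if n else np.nan
        rows.append((level, 100.0 * level, obs, n_below, n))
    table = pd.DataFrame(
        rows, columns=["level", "expected_pct", "observed_pct", "n_below", "n"]
    )
    return CoverageReport(table=table, n_used=n, n_excluded=n_excluded)


def render_chart(chart, image_path, overlay_data=None, csv_path=None, title=None):
    """Write a labeled centile-fan figure (PNG/SVG by extension) and optionally
    the chart CSV.  Returns the matplotlib figure for further styling."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for j, level in enumerate(chart.levels):
        is_median = abs(level - 0.5) < 1e-9
        ax.plot(
            chart.days,
            chart.values[:, j],
            lw=2.0 if is_median else 1.2,
            color="C0" if is_median else "C7",
            label=f"{round(level * 100)}th",
        )
        ax.annotate(
            f"{round(level * 100)}",
            (chart.days[-1], chart.values[-1, j]),
            textcoords="offset points",
            xytext=(4, -3),
            fontsize=8,
        )
    if overlay_data is not None:
        frame = overlay_data.frame if hasattr(overlay_data, "frame") else overlay_data
        ax.scatter(
            frame["day_post_op"],
            frame["flexion_deg"],
            s=8,
            alpha=0.35,
            color="C3",
            label="observations",
        )
    ax.set_xlabel("days post-surgery")
    ax.set_ylabel("knee flexion AROM (degrees)")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    if csv_path is not None:
        chart.to_csv(csv_path)
    plt.close(fig)
    return fig
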