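"""Survival-curve I/O, comparison and trial pooling.

Model output and registry/trial curves meet here: curves live on a monthly
grid (the networks produce one point per 6-month slice), agreement is
summarized as the mean absolute difference at the five yearly points 12,
24, 36, 48 and 60 months (linear interpolation in between), and
multi-study trial curves can be pooled into a sample-size-weighted mean
with a normal-approximation 95% confidence band.

No registry or trial data is bundled; curves are user-supplied CSVs with a
``month,survival`` header and proportions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import SurvivalCurve

__all__ = [
    "SurvivalCurve",
    "PooledTrialCurve",
    "YEARLY_POINTS",
    "mean_absolute_yearly_difference",
    "pool_trial_curves",
    "read_curve_csv",
    "write_curve_csv",
    "marginals_to_frame",
]

YEARLY_POINTS = (12.0, 24.0, 36.0, 48.0, 60.0)


class CurveFormatError(ValueError):
    """A curve CSV failed to parse; the message carries the line number."""


@dataclass
class PooledTrialCurve:
    months: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    total_n: int
    per_study: list[tuple[SurvivalCurve, int]]

    def as_curve(self, label: str = "pooled") -> SurvivalCurve:
        return SurvivalCurve(self.months, self.mean, label)


def _evaluate(curve: SurvivalCurve, months: np.ndarray) -> np.ndarray:
    lo, hi = curve.months[0], curve.months[-1]
    if months.min() < lo - 1e-9 or months.max() > hi + 1e-9:
        raise ValueError(
            f"curve {curve.label!r} covers [{lo:g}, {hi:g}] months and cannot be "
            f"evaluated over [{months.min():g}, {months.max():g}]"
        )
    return np.interp(months, curve.months, curve.survival)


def mean_absolute_yearly_difference(
    predicted: SurvivalCurve,
    reference: SurvivalCurve,
    horizon_months: float = 60.0,
) -> float:
    """Mean |predicted − reference| over the yearly points up to the horizon,
    in percentage points.

    With the default 60-month horizon this is the mean over the five yearly
    survival rates at months 12..60; both curves are linearly interpolated
    onto those points.  Symmetric in its arguments.
    """
    points = np.array([m for m in YEARLY_POINTS if m <= horizon_months + 1e-9])
    if len(points) == 0:
        raise ValueError(f"horizon {horizon_months} months contains no yearly point")
    diff = np.abs(_evaluate(predicted, points) - _evaluate(reference, points))
    return float(diff.mean() * 100.0)


def pool_trial_curves(per_study: list[tuple[SurvivalCurve, int]]) -> PooledTrialCurve:
    """Sample-size-weighted mean of aligned study curves with a 95% CI.

    All curves must share the same time grid.  The confidence band is the
    normal approximation for the pooled proportion at total sample size,
    ``p ± 1.96·sqrt(p(1−p)/Σn)``, clipped to [0, 1]; a single study thus
    gets its binomial CI.  The band narrows as total n grows.
    """
    if not per_study:
        raise ValueError("at least one study is required")
    months = per_study[0][0].months
    for curve, n_i in per_study:
        if n_i <= 0:
            raise ValueError(f"study {curve.label!r} has non-positive sample size {n_i}")
        if len(curve.months) != len(months) or not np.allclose(curve.months, months):
            raise ValueError(
                f"study {curve.label!r} is on a different time grid; "
                "interpolate the inputs onto a common grid first"
            )
    weights = np.array([n for _, n in per_study], dtype=float)
    values = np.stack([c.survival for c, _ in per_study])
    total = weights.sum()
    mean = weights @ values / total
    half = 1.96 * np.sqrt(mean * (1.0 - mean) / total)
    return PooledTrialCurve(
        months=np.asarray(months, dtype=float),
        mean=mean,
        lower=np.clip(mean - half, 0.0, 1.0),
        upper=np.clip(mean + half, 0.0, 1.0),
        total_n=int(total),
        per_study=list(per_study),
    )


def read_curve_csv(path: str | Path) -> SurvivalCurve:
    """Read a ``month,survival`` CSV; errors carry 1-based line numbers."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or [c.strip() for c in lines[0].split(",")[:2]] != ["month", "survival"]:
        raise CurveFormatError(f"{path}: line 1: expected header 'month,survival'")
    months: list[float] = []
    values: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise CurveFormatError(f"{path}: line {lineno}: expected 'month,survival'")
        try:
            m, s = float(parts[0]), float(parts[1])
        except ValueError:
            raise CurveFormatError(
                f"{path}: line {lineno}: non-numeric value in {line!r}"
            ) from None
        if not 0.0 <= s <= 1.0:
            raise CurveFormatError(
                f"{path}: line {lineno}: survival {s} outside [0, 1]"
            )
        if months and m <= months[-1]:
            raise CurveFormatError(
                f"{path}: line {lineno}: month {m:g} not after {months[-1]:g} "
                "(time must be strictly increasing)"
            )
        months.append(m)
        values.append(s)
    if not months:
        raise CurveFormatError(f"{path}: no data rows")
    return SurvivalCurve(np.array(months), np.array(values), label=path.stem)


def write_curve_csv(curve: SurvivalCurve, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("month,survival\n")
        for m, s in zip(curve.months, curve.survival):
            fh.write(f"{m:.12g},{s:.12g}\n")


def marginals_to_frame(trajectories: dict) -> pd.DataFrame:
    """Flatten marginal trajectories to (slice, variable, state, probability)."""
    records = []
    for var, traj in trajectories.items():
        for t in range(traj.probabilities.shape[0]):
            for i, state in enumerate(traj.states):
                records.append(
                    {
                        "slice": t,
                        "variable": var,
                        "state": state,
                        "probability": traj.probabilities[t, i],
                    }
                )
    return pd.DataFrame.from_records(records)
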