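"""CPT-elicitation calculus.

Clinical literature typically states event probabilities over long horizons
("30% of patients die of other cancers within 25 years") while a two-slice
temporal model needs the per-slice probability.  Two conversions are
provided, both parameterised in *unit periods* (one unit period = one model
slice, 6 months for the shipped networks):

- :func:`rescale_probability` — the linearized hazard form
  ``P_k = -(k/m) * ln(1 - P_m)``, i.e. the cumulative hazard over the known
  horizon spread uniformly over its ``m`` periods.  Unbounded for large
  ``P_m``; the result is clamped to [0, 1] with a warning.
- :func:`rescale_probability_exact` — the constant-hazard survival form
  ``P_k = 1 - (1 - P_m)**(k/m)``, the identity at k = m.  The two agree to
  first order for small probabilities.

Expert statements of the kind "event E occurs r times more often in stratum
S" are applied with :func:`odds_adjust`, by default on the odds scale
(bounded and symmetric); a risk-ratio scale is available via ``scale``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "HorizonProbability",
    "UnitProbability",
    "rescale_probability",
    "rescale_probability_exact",
    "odds_adjust",
    "ElicitationWarning",
]


class ElicitationWarning(UserWarning):
    """Recorded when a rescaled probability had to be clamped into [0, 1]."""


@dataclass(frozen=True)
class HorizonProbability:
    """A probability ``p`` known over a horizon of ``horizon`` unit periods."""

    p: float
    horizon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"horizon probability must lie in [0, 1), got {self.p}")
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")


@dataclass(frozen=True)
class UnitProbability:
    """A per-period probability ``p`` over a period of ``period`` unit periods."""

    p: float
    period: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {self.p}")
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")


def _as_horizon(source, horizon) -> HorizonProbability:
    if isinstance(source, HorizonProbability):
        return source
    if horizon is None:
        raise TypeError("horizon (m, in unit periods) is required with a bare probability")
    return HorizonProbability(float(source), float(horizon))


def rescale_probability(
    source: HorizonProbability | float, k: float = 1.0, *, horizon: float | None = None
) -> UnitProbability:
    """Linearized rescaling of a horizon probability to ``k`` unit periods.

    ``rescale_probability(0.3, horizon=50)`` converts a 30% risk stated over
    50 slices (25 years of 6-month slices) to a single slice: 0.00713...

    Values above 1 (possible because the linearized form is unbounded) are
    clamped to 1.0 and an :class:`ElicitationWarning` is emitted.
    """
    src = _as_horizon(source, horizon)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    value = -(k / src.horizon) * math.log1p(-src.p)
    if value > 1.0:
        warnings.warn(
            f"rescaled probability {value:.6g} clamped to 1.0 "
            f"(p={src.p}, m={src.horizon}, k={k})",
            ElicitationWarning,
            stacklevel=2,
        )
        value = 1.0
    return UnitProbability(min(max(value, 0.0), 1.0), k)


def rescale_probability_exact(
    source: HorizonProbability | float, k: float = 1.0, *, horizon: float | None = None
) -> UnitProbability:
    """Constant-hazard rescaling ``1 - (1 - p)**(k/m)``; identity at k = m."""
    src = _as_horizon(source, horizon)
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    value = -math.expm1((k / src.horizon) * math.log1p(-src.p))
    return UnitProbability(min(max(value, 0.0), 1.0), k)


def odds_adjust(base: float, multiplier: float, *, scale: str = "odds") -> float:
    """Apply an expert "r times more often" multiplier to a base probability.

    ``scale='odds'`` (default) multiplies the odds: the result is the
    probability whose odds are ``multiplier * base / (1 - base)``; bounded,
    monotone in both arguments, with 0 and 1 as fixed points.
    ``scale='risk'`` multiplies the probability directly, capped at 1.
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base probability must lie in [0, 1], got {base}")
    if multiplier < 0:
        raise ValueError(f"multiplier must be non-negative, got {multiplier}")
    if scale == "odds":
        if base == 1.0:
            return 1.0 if multiplier > 0 else 0.0
        num = multiplier * base
        return num / (num + (1.0 - base))
    if scale == "risk":
        return min(base * multiplier, 1.0)
    raise ValueError(f"scale must be 'odds' or 'risk', got {scale!r}")
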