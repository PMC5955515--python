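"""Oxygen-dependent Eastern Baltic cod egg survival.

The dose-response curve, fitted elsewhere to incubation experiments,
gives the pre-hatch survival probability as a function of ambient oxygen
content x (ml/l):

    y = scale * (1 - exp(-a * x)) ** b,    a = 0.71, b = 11.63

a sigmoid with near-total mortality at 2 ml/l, ~50% mortality at 4 ml/l
and <10% mortality at 7 ml/l.  Survival is reported on the 0-100% scale
here; indicator regressions use the 0-1 probability scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import MonthlySeries


@dataclass(frozen=True)
class SurvivalCurveParams:
    rate: float = 0.71       # per (ml/l)
    exponent: float = 11.63  # dimensionless
    scale: float = 100.0     # percent

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.exponent <= 0:
            raise ValueError("rate and exponent must be positive")


DEFAULT_PARAMS = SurvivalCurveParams()


def egg_survival(oxygen, params: SurvivalCurveParams = DEFAULT_PARAMS):
    """Survival (%) at oxygen content ``oxygen`` (ml/l, scalar or array).

    Strictly increasing in oxygen, 0 at 0 and approaching ``scale`` from
    below; NaN propagates.
    """
    x = np.asarray(oxygen, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(x < 0):
            raise ValueError("oxygen content must be >= 0")
    y = params.scale * (1.0 - np.exp(-params.rate * x)) ** params.exponent
    return float(y) if np.isscalar(oxygen) else y


def half_survival_oxygen(params: SurvivalCurveParams = DEFAULT_PARAMS) -> float:
    """Closed-form oxygen content at 50% survival:
    x50 = -ln(1 - 2^(-1/b)) / a  (~4.0 ml/l at the default parameters)."""
    return float(-np.log(1.0 - 2.0 ** (-1.0 / params.exponent)) / params.rate)


def survival_series(oxygen: MonthlySeries,
                    params: SurvivalCurveParams = DEFAULT_PARAMS) -> MonthlySeries:
    """Elementwise survival (%) of a monthly oxygen series; masked months
    and 'level absent' flags propagate unchanged."""
    vals = oxygen.data.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    ok = np.isfinite(vals)
    out[ok] = egg_survival(vals[ok], params)
    prov = dict(oxygen.provenance)
    prov["derived"] = "egg_survival"
    return MonthlySeries(data=pd.Series(out, index=oxygen.data.index),
                         units="%", provenance=prov,
                         absent=None if oxygen.absent is None else oxygen.absent.copy())
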