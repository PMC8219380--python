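"""Ligand potency from dose-response curves.

Potency PX is the ligand dose producing X% activation (15% for CD69, 10%
for IL-2 — thresholds low enough to include weak ligands yet above assay
noise).  Two extraction routes are provided:

- fit a four-parameter sigmoid on the linear response scale and invert it
  analytically at the threshold (primary route for own data);
- linearly interpolate tabulated curve points in (log10 dose, response)
  space (literature route, where only plotted points are available).

Potencies that would exceed the highest tested dose are never returned:
extrapolated potency systematically inflates the apparent discrimination
power, so such ligands come back flagged ``"extrapolated"``.  Ligands whose
response never reaches the threshold are flagged ``"below_threshold"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy.optimize import least_squares

from .spr import FitError


@dataclass(frozen=True)
class HillFit:
    """Four-parameter sigmoid R(x) = Emin + (Emax-Emin)/(1+(EC50/x)^H)."""

    emin: float
    emax: float
    ec50: float
    hill: float
    sse: float

    def response(self, dose):
        x = np.asarray(dose, dtype=float)
        return self.emin + (self.emax - self.emin) / (1.0 + (self.ec50 / x) ** self.hill)


@dataclass(frozen=True)
class PotencyResult:
    """PX in dose units, or an exclusion flag with the rule that fired."""

    px: float | None
    flag: str = ""  # "", "below_threshold", "extrapolated", "no_crossing"

    @property
    def excluded(self) -> bool:
        return self.flag != ""


def _sigmoid(x, emin, emax, ec50, hill):
    return emin + (emax - emin) / (1.0 + (ec50 / x) ** hill)


def fit_hill(doses, responses) -> HillFit:
    """Least-squares four-parameter sigmoid fit on the linear % scale."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 5:
        raise FitError("need >= 5 dose points")
    if np.any(x <= 0):
        raise ValueError("doses must be > 0")
    if np.ptp(y) == 0:
        raise FitError("flat response")
    model = Model(_sigmoid, independent_vars=["x"])
    mid = float(np.sqrt(x.min() * x.max()))
    params = model.make_params(emin=float(y.min()), emax=float(y.max()),
                               ec50=mid, hill=1.0)
    params["ec50"].set(min=x.min() * 1e-6, max=x.max() * 1e6)
    params["hill"].set(min=1e-3, max=20.0)
    res = model.fit(y, params, x=x,
                    fit_kws={"xtol": 1e-14, "ftol": 1e-14, "gtol": 1e-14})
    if not res.success:
        raise FitError("sigmoid fit failed")
    p = np.array([res.params[k].value for k in ("emin", "emax", "ec50", "hill")])
    # polish to machine precision (matters for noiseless round-trips)
    sol = least_squares(lambda q: _sigmoid(x, *q) - y, p, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if sol.cost <= 0.5 * np.sum((res.residual) ** 2) and sol.x[2] > 0 \
            and sol.x[3] > 0:
        p = sol.x
    fit = HillFit(float(p[0]), float(p[1]), float(p[2]), float(p[3]),
                  float(np.sum((_sigmoid(x, *p) - y) ** 2)))
    if fit.emax <= fit.emin:
        raise FitError("degenerate sigmoid (Emax <= Emin)")
    return fit


def interpolate_potency(fit: HillFit, threshold: float,
                        max_dose: float) -> PotencyResult:
    """Analytic inversion of the fitted sigmoid at the threshold X.

    PX = EC50 / ((Emax-Emin)/(X-Emin) - 1)^(1/H) for Emin < X < Emax.
    Returns ``below_threshold`` when the curve never reaches X, and
    ``extrapolated`` when PX exceeds the highest tested dose.
    """
    if threshold <= fit.emin:
        raise ValueError(
            f"threshold {threshold}% is at or below the fitted baseline "
            f"({fit.emin:.3g}%)")
    if fit.emax <= threshold:
        return PotencyResult(None, "below_threshold")
    ratio = (fit.emax - fit.emin) / (threshold - fit.emin) - 1.0
    px = fit.ec50 / ratio ** (1.0 / fit.hill)
    if px > max_dose:
        return PotencyResult(None, "extrapolated")
    return PotencyResult(float(px))


def potency_from_points(doses, responses, threshold: float) -> PotencyResult:
    """Literature-mode PX: linear interpolation in (log10 dose, response).

    Finds the first pair of consecutive points straddling the threshold
    (dose-response figures are log-scaled, so interpolation is done in
    log10 dose).  Warns if the curve crosses the threshold more than once.
    No crossing within the tested range -> flagged ``no_crossing``.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 points")
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise ValueError("doses must be > 0 and strictly increasing")
    above = y >= threshold
    crossings = [i for i in range(len(x) - 1) if above[i] != above[i + 1]]
    if not crossings:  # curve never crosses the threshold in-range
        return PotencyResult(None, "no_crossing")
    if len(crossings) > 1:
        warnings.warn("response crosses the threshold more than once; "
                      "using the first crossing", stacklevel=2)
    i = crossings[0]
    lx0, lx1 = np.log10(x[i]), np.log10(x[i + 1])
    frac = (threshold - y[i]) / (y[i + 1] - y[i])
    return PotencyResult(float(10.0 ** (lx0 + frac * (lx1 - lx0))))
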