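"""Steady-state SPR affinity estimation with a constrained-Bmax option.

The standard protocol fits the Langmuir isotherm B = Bmax*[TCR]/(KD+[TCR])
with both KD and Bmax free.  For low-affinity interactions the titration
cannot be pushed to saturation (soluble TCR aggregates at high
concentration), the SSE surface develops a Bmax/KD ridge, and the free fit
over-fits: very different (KD, Bmax) pairs describe the data equally well.

The constrained method breaks the ridge with an independent estimate of
Bmax: the conformation-sensitive W6/32 antibody binds only correctly
folded pMHC, so its plateau response Rmax is a proxy for the active site
density.  An empirical standard curve Bmax = slope*Rmax + intercept,
built from saturating (max[TCR]/KD >= 2.5) free fits, converts Rmax into a
fixed Bmax, leaving KD as the only free parameter.  Constrained KDs above
20 uM are reported; below that the free fit is used (both methods agree
there and the free fit avoids standard-curve error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy.optimize import minimize_scalar
from scipy.stats import linregress


class FitError(RuntimeError):
    """A least-squares fit failed or its input was degenerate."""


@dataclass(frozen=True)
class BindingCurve:
    """One steady-state SPR titration (double-referenced)."""

    ligand_id: str
    T: np.ndarray  # TCR concentrations, uM, strictly increasing
    B: np.ndarray  # responses, RU
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "B", B)
        if len(T) != len(B):
            raise ValueError("T and B must have equal length")
        if len(T) < 4:
            raise ValueError("need >= 4 titration points")
        if np.any(T <= 0) or np.any(np.diff(T) <= 0):
            raise ValueError("T must be strictly positive and increasing")


@dataclass(frozen=True)
class LangmuirFit:
    ligand_id: str
    kd: float           # uM
    bmax: float         # RU
    method: str         # "free" | "constrained"
    sse: float
    saturation_ratio: float  # max(T) / fitted KD


@dataclass(frozen=True)
class W632Fit:
    ligand_id: str
    rmax: float  # RU
    kt: float    # s, nuisance
    sse: float


@dataclass(frozen=True)
class StandardCurve:
    """Linear map from W6/32 Rmax to TCR Bmax, interpolation-only."""

    slope: float
    intercept: float
    n_points: int
    rmax_min: float
    rmax_max: float

    def bmax_for(self, rmax: float) -> float:
        if not (self.rmax_min <= rmax <= self.rmax_max):
            raise ValueError(
                f"Rmax {rmax:.3g} RU outside standard curve range "
                f"[{self.rmax_min:.3g}, {self.rmax_max:.3g}]; "
                "extrapolation is refused")
        return self.slope * rmax + self.intercept


def _langmuir(T, kd, bmax):
    return bmax * T / (kd + T)


def double_reference(signal, reference, buffer_before, buffer_after):
    """Double-reference an SPR series.

    Subtracts the reference flow-cell signal, then the mean of the two
    flanking (already reference-subtracted) buffer injections, removing
    flow-cell differences and slow drifts.
    """
    arrs = [np.asarray(a, dtype=float)
            for a in (signal, reference, buffer_before, buffer_after)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all series must have the same length")
    sig, ref, b0, b1 = arrs
    return sig - ref - 0.5 * (b0 + b1)


def fit_langmuir_free(curve: BindingCurve) -> LangmuirFit:
    """Two-parameter Langmuir fit (KD and Bmax both free, both > 0)."""
    if np.ptp(curve.B) == 0:
        raise FitError(f"{curve.ligand_id}: flat binding curve")
    model = Model(_langmuir, independent_vars=["T"])
    params = model.make_params(kd=float(np.median(curve.T)),
                               bmax=1.2 * float(np.max(curve.B)))
    params["kd"].set(min=1e-9)
    params["bmax"].set(min=1e-9)
    res = model.fit(curve.B, params, T=curve.T,
                    fit_kws={"xtol": 1e-14, "ftol": 1e-14, "gtol": 1e-14})
    if not res.success:
        raise FitError(f"{curve.ligand_id}: free Langmuir fit failed")
    kd = float(res.params["kd"].value)
    bmax = float(res.params["bmax"].value)
    return LangmuirFit(curve.ligand_id, kd, bmax, "free",
                       float(np.sum(res.residual ** 2)),
                       float(np.max(curve.T)) / kd)


def _w632_model(t, rmax, kt):
    return rmax * t / (kt + t)


def fit_w632_rmax(ligand_id: str, time_s, response) -> W632Fit:
    """Fit the empirical W6/32 binding model R = Rmax*t/(Kt+t).

    Kt is a nuisance parameter; only the plateau Rmax feeds the standard
    curve.
    """
    t = np.asarray(time_s, dtype=float)
    r = np.asarray(response, dtype=float)
    if len(t) < 5:
        raise FitError("need >= 5 time points")
    if np.any(t <= 0):
        raise ValueError("time points must be > 0")
    model = Model(_w632_model, independent_vars=["t"])
    params = model.make_params(rmax=float(np.max(r)), kt=float(np.median(t)))
    params["rmax"].set(min=1e-9)
    params["kt"].set(min=0.0)
    res = model.fit(r, params, t=t,
                    fit_kws={"xtol": 1e-14, "ftol": 1e-14, "gtol": 1e-14})
    if not res.success:
        raise FitError(f"{ligand_id}: W6/32 fit failed")
    return W632Fit(ligand_id, float(res.params["rmax"].value),
                   float(res.params["kt"].value),
                   float(np.sum(res.residual ** 2)))


def build_standard_curve(pairs: list[tuple[float, LangmuirFit]],
                         saturation_ratio: float = 2.5) -> StandardCurve:
    """OLS line Bmax = slope*Rmax + intercept over saturating free fits.

    Only pairs whose free fit reached max(T)/KD >= ``saturation_ratio``
    are retained — below that the fitted Bmax itself is unreliable.
    """
    for _, fit in pairs:
        if fit.method != "free":
            raise ValueError("standard curve requires free-method fits")
    kept = [(rmax, fit) for rmax, fit in pairs
            if fit.saturation_ratio >= saturation_ratio]
    if len(kept) < 3:
        raise FitError(
            f"only {len(kept)} saturating pairs (need >= 3) for standard curve")
    rmaxes = np.array([r for r, _ in kept])
    bmaxes = np.array([f.bmax for _, f in kept])
    ols = linregress(rmaxes, bmaxes)
    return StandardCurve(float(ols.slope), float(ols.intercept), len(kept),
                         float(rmaxes.min()), float(rmaxes.max()))


def fit_langmuir_constrained(curve: BindingCurve, std: StandardCurve,
                             rmax: float) -> LangmuirFit:
    """One-parameter Langmuir fit with Bmax fixed from the standard curve.

    Bmax := slope*rmax + intercept (interpolation only); the SSE is then
    minimised over log10(KD) alone, which is well conditioned even for
    non-saturating curves.
    """
    bmax = std.bmax_for(rmax)
    if bmax <= 0:
        raise FitError("standard curve gave non-positive Bmax")

    def sse(log_kd: float) -> float:
        pred = _langmuir(curve.T, 10.0 ** log_kd, bmax)
        return float(np.sum((curve.B - pred) ** 2))

    res = minimize_scalar(sse, bounds=(-6.0, 9.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise FitError(f"{curve.ligand_id}: constrained fit failed")
    kd = float(10.0 ** res.x)
    return LangmuirFit(curve.ligand_id, kd, float(bmax), "constrained",
                       float(res.fun), float(np.max(curve.T)) / kd)


def select_reported_kd(free: LangmuirFit,
                       constrained: LangmuirFit,
                       kd_switch_threshold: float = 20.0) -> tuple[float, str]:
    """Reporting rule: constrained KD strictly above the switch threshold
    (default 20 uM) is reported; otherwise the free-fit KD is."""
    if free.ligand_id != constrained.ligand_id:
        raise ValueError("fits are for different ligands")
    if constrained.kd > kd_switch_threshold:
        return constrained.kd, "constrained"
    return free.kd, "free"


def replicate_cv(kds) -> float:
    """Coefficient of variation (sample SD / mean) of replicate KDs."""
    arr = np.asarray(kds, dtype=float)
    if len(arr) < 2:
        raise ValueError("need >= 2 replicates")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean KD must be > 0")
    return float(arr.std(ddof=1) / mean)
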