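"""Kinetic proofreading (KP) model of TCR antigen discrimination.

A pMHC ligand L binds a TCR R at rate ``kon`` to form a complex C0, which
must traverse ``N`` sequential biochemical steps, each at rate ``kp``,
before it signals (state CN).  The ligand can dissociate at rate ``koff``
from any step, resetting the chain.  The proofreading time delay
``tau_KP = N / kp`` penalises fast-dissociating (low-affinity) ligands and
is the mechanistic origin of enhanced discrimination.

This module provides the closed-form steady state of the reaction chain,
the closed-form ligand potency it implies, the log10 potency ``rho`` used
for fitting, and the deterministic sensitivity/discrimination constraints
used for phase maps.

Conventions: KD in uM, kon in uM^-1 s^-1 (default 0.0447, the average
TCR/pMHC on-rate at 37 C), koff and kp in s^-1.  The observables lambda
(activation threshold as a fraction of R0), gamma (ligand-scale
conversion) and delta (affinity-scale conversion) are dimensionless fit
constants; internally the orthogonalised forms lambda_hat = lambda/gamma
and delta_hat = delta/gamma are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_KON = 0.0447
"""Fixed TCR/pMHC on-rate (uM^-1 s^-1), average of NYE peptide variants at 37 C."""


class UnreachableLigandError(ValueError):
    """The activation threshold cannot be reached at any ligand dose.

    Raised when lambda * (1 + koff/kp)^N >= 1: even at full receptor
    occupancy the concentration of signalling complexes CN stays below the
    threshold lambda*R0, so the potency is undefined.
    """


@dataclass(frozen=True)
class KPSystem:
    """Parameters of one kinetic-proofreading reaction system.

    N may be fractional for the analytic formulas; stochastic simulation
    requires an integer.  L0 and R0 are total ligand and receptor amounts
    (counts or concentrations, as long as kon's units agree).
    """

    N: float
    kp: float
    kon: float
    koff: float
    L0: float
    R0: float

    def __post_init__(self) -> None:
        for name in ("kp", "kon", "koff", "L0", "R0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N}")
        if self.kp == 0 and self.N > 0:
            raise ValueError("kp must be > 0 when N > 0")


@dataclass(frozen=True)
class KPObservable:
    """Threshold/conversion constants linking the KP model to measured potency.

    lam is the activation threshold (fraction of R0 that must be in the
    final step), gamma converts model ligand numbers to experimental doses
    and delta converts model affinity to experimental KD.  lambda_hat and
    delta_hat are the orthogonalised combinations actually fitted.
    """

    lam: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.gamma > 0 and self.delta > 0):
            raise ValueError("lam, gamma, delta must all be > 0")

    @property
    def lambda_hat(self) -> float:
        return self.lam / self.gamma

    @property
    def delta_hat(self) -> float:
        return self.delta / self.gamma


def steady_state(sys: KPSystem) -> tuple[float, float]:
    """Closed-form steady state (Ctot, CN) of the proofreading chain.

    Ctot is the root of the bimolecular binding quadratic under the two
    conservation laws; the chain then thins Ctot geometrically so that
    CN = (1 + koff/kp)^(-N) * Ctot.  kon = 0 returns (0, 0).
    """
    if sys.kon == 0.0:
        return 0.0, 0.0
    kd = sys.koff / sys.kon
    s = sys.L0 + sys.R0 + kd
    disc = s * s - 4.0 * sys.L0 * sys.R0
    # clamp tiny negative round-off when koff == 0 and L0 == R0
    ctot = 0.5 * (s - math.sqrt(max(disc, 0.0)))
    if sys.N == 0:
        return ctot, ctot
    cn = ctot * (1.0 + sys.koff / sys.kp) ** (-sys.N)
    return ctot, cn


def koff_from_kd(kd: float, kon: float = DEFAULT_KON) -> float:
    """Dissociation rate implied by KD under a fixed on-rate, koff = kon*KD."""
    if kd <= 0:
        raise ValueError(f"KD must be > 0, got {kd}")
    return kon * kd


def potency_x(N: float, kp: float, lam: float, gamma: float, delta: float,
              kd: float, kon: float = DEFAULT_KON) -> float:
    """Closed-form relative ligand dose x = L0/R0 reaching the threshold.

    Derived by inverting the steady-state relation 2*lam*B = 1 + gamma*x +
    delta*KD - sqrt((1 + gamma*x + delta*KD)^2 - 4*gamma*x) with
    B = (1 + koff/kp)^N; valid (and positive) iff lam*B < 1.

    Raises :class:`UnreachableLigandError` when lam*B >= 1.
    """
    koff = koff_from_kd(kd, kon)
    B = (1.0 + koff / kp) ** N
    if lam * B >= 1.0:
        raise UnreachableLigandError(
            f"threshold unreachable: lam*(1+koff/kp)^N = {lam * B:.4g} >= 1")
    return (lam * B / gamma) * (1.0 - delta * kd / (lam * B - 1.0))


def log_potency_rho(N: float, kp: float, lambda_hat: float, gamma: float,
                    delta_hat: float, kd, kon: float = DEFAULT_KON):
    """Log10 ligand potency rho of the KP model (the fitted quantity).

    rho = log10(lambda_hat) + N*log10(1 + koff/kp)
        + log10(1 - delta_hat*KD / (lambda_hat*(1+koff/kp)^N - 1/gamma))

    with koff = kon*KD.  Algebraically identical to log10(potency_x) under
    lambda_hat = lam/gamma, delta_hat = delta/gamma.  Accepts scalar or
    array KD; unreachable ligands (lambda_hat*gamma*B >= 1) yield NaN for
    arrays and raise :class:`UnreachableLigandError` for scalars.
    """
    kd_arr = np.asarray(kd, dtype=float)
    scalar = kd_arr.ndim == 0
    kd_arr = np.atleast_1d(kd_arr)
    if np.any(kd_arr <= 0):
        raise ValueError("KD must be > 0")
    koff = kon * kd_arr
    one_plus = 1.0 + koff / kp
    B = one_plus ** N
    reachable = lambda_hat * gamma * B < 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 1.0 - delta_hat * kd_arr / (lambda_hat * B - 1.0 / gamma)
        rho = (np.log10(lambda_hat) + N * np.log10(one_plus) + np.log10(arg))
    rho = np.where(reachable, rho, np.nan)
    if scalar:
        if not reachable[0]:
            raise UnreachableLigandError(
                "threshold unreachable for this ligand (lam*(1+koff/kp)^N >= 1)")
        return float(rho[0])
    return rho


def sensitivity_ok(N: float, kp: float, koff1: float, lam: float) -> bool:
    """Deterministic sensitivity constraint for a single high-affinity ligand.

    A lone agonist (L0 = 1) must push the final-step occupancy above the
    threshold: (1 + koff1/kp)^(-N) > lam, using Ctot ~ min(L0, R0) = 1.
    """
    if N == 0:
        return 1.0 > lam
    return (1.0 + koff1 / kp) ** (-N) > lam

def discrimination_ok(N: float, kp: float, koff1: float, lam: float,
                      alpha: float, L_high: float = 10000.0,
                      R0: float = 30000.0) -> bool:
    """Deterministic discrimination constraint at discrimination power alpha.

    A ligand presented at L_high copies but binding Delta-fold weaker, with
    Delta = L_high^(1/alpha), must stay below threshold:
    min(L_high, R0) * (1 + Delta*koff1/kp)^(-N) < lam.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    delta_a = L_high ** (1.0 / alpha)
    base = min(L_high, R0)
    if N == 0:
        return base < lam
    return base * (1.0 + delta_a * koff1 / kp) ** (-N) < lam
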