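"""Discrete stochastic simulation of the KP chain and binary phase maps.

At single-molecule ligand numbers the deterministic steady state is not
guaranteed to describe the model, so sensitivity and discrimination are
also assessed by exact Gillespie simulation of the reaction network

    L + R -> C0        (propensity kon * L * R)
    Ci -> Ci+1         (kp * Ci,   i = 0..N-1)
    Ci -> L + R        (koff * Ci, i = 0..N)

with integer copy numbers.  For each point of an (N, tau = 1/kp) grid two
scenarios are simulated to a fixed termination time and the ensemble mean
occupancy of the final step <CN> is compared with the activation
threshold lambda:

- sensitivity: a single high-affinity ligand (L0 = 1, koff = koff1 = 1/s)
  must give <CN> > lambda;
- discrimination: a ligand presented at Delta_L copies but binding
  Delta_A = Delta_L^(1/alpha)-fold weaker must stay below, <CN> < lambda.

The paper-scale protocol (defaults) uses 250 realisations to t = 100 s,
lambda = 0.1, R0 = 30000, Delta_L = 10000.  The per-molecule kon is chosen
so that kon*R0 = 100*koff1, making single-agonist occupancy >99% and
matching the deterministic Ctot ~ min(L0, R0) approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from . import kp_model


@dataclass(frozen=True)
class StochasticConfig:
    """Protocol for the stochastic phase-map scenarios."""

    n_realisations: int = 250
    t_end: float = 100.0
    lambda_threshold: float = 0.1
    R0: int = 30000
    L_high: int = 10000
    koff1: float = 1.0
    #: per-molecule kon = kon_occupancy_factor * koff1 / R0
    kon_occupancy_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.n_realisations < 1 or self.t_end <= 0:
            raise ValueError("need n_realisations >= 1 and t_end > 0")
        if self.lambda_threshold <= 0 or self.R0 < 1 or self.L_high < 1:
            raise ValueError("invalid scenario sizes")
        if self.koff1 <= 0 or self.kon_occupancy_factor <= 0:
            raise ValueError("koff1 and kon_occupancy_factor must be > 0")

    @property
    def kon(self) -> float:
        return self.kon_occupancy_factor * self.koff1 / self.R0


@njit(cache=True)
def _ssa_nb(n, kp, kon, koff, l0, r0, t_end, seed):
    """One exact SSA realisation; returns (L, R, C[0..N]) at t_end."""
    np.random.seed(seed)
    L = l0
    R = r0
    C = np.zeros(n + 1, dtype=np.int64)
    ctot = 0
    t = 0.0
    while True:
        a_bind = kon * L * R
        a_step = kp * (ctot - C[n])
        a_off = koff * ctot
        a_tot = a_bind + a_step + a_off
        if a_tot <= 0.0:
            break
        t += np.random.exponential(1.0 / a_tot)
        if t > t_end:
            break
        u = np.random.random() * a_tot
        if u < a_bind:
            L -= 1
            R -= 1
            C[0] += 1
            ctot += 1
        elif u < a_bind + a_step:
            v = (u - a_bind) / kp
            acc = 0.0
            for i in range(n):
                acc += C[i]
                if v < acc:
                    C[i] -= 1
                    C[i + 1] += 1
                    break
        else:
            v = (u - a_bind - a_step) / koff
            acc = 0.0
            for i in range(n + 1):
                acc += C[i]
                if v < acc:
                    C[i] -= 1
                    ctot -= 1
                    L += 1
                    R += 1
                    break
    return L, R, C


@njit(cache=True)
def _ensemble_cn_nb(n, kp, kon, koff, l0, r0, t_end, seeds):
    out = np.empty(seeds.size, dtype=np.float64)
    for k in range(seeds.size):
        _, _, C = _ssa_nb(n, kp, kon, koff, l0, r0, t_end, seeds[k])
        out[k] = C[n]
    return out


def gillespie_kp(sys: kp_model.KPSystem, t_end: float,
                 seed: int) -> tuple[int, int, np.ndarray]:
    """One exact stochastic realisation of the KP chain.

    Returns the final state (L, R, C) at ``t_end``; ``C[N]`` is the count
    of signalling complexes.  Requires integer N, L0, R0.
    """
    if sys.N != int(sys.N):
        raise ValueError("stochastic simulation requires integer N")
    if sys.L0 != int(sys.L0) or sys.R0 != int(sys.R0):
        raise ValueError("stochastic simulation requires integer counts")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    L, R, C = _ssa_nb(int(sys.N), sys.kp, sys.kon, sys.koff,
                      int(sys.L0), int(sys.R0), float(t_end),
                      int(seed) % (2 ** 31 - 1))
    return int(L), int(R), np.asarray(C)


def ensemble_mean_cn(sys: kp_model.KPSystem, n_realisations: int,
                     t_end: float, seed: int) -> tuple[float, float]:
    """Mean and standard error of CN(t_end) over independent realisations."""
    if sys.N != int(sys.N):
        raise ValueError("stochastic simulation requires integer N")
    rng = np.random.RandomState(seed)
    seeds = rng.randint(0, 2 ** 31 - 1, size=n_realisations)
    cns = _ensemble_cn_nb(int(sys.N), sys.kp, sys.kon, sys.koff,
                          int(sys.L0), int(sys.R0), float(t_end), seeds)
    mean = float(cns.mean())
    se = float(cns.std(ddof=1) / np.sqrt(n_realisations)) if n_realisations > 1 else 0.0
    return mean, se


@dataclass(frozen=True)
class PhaseMapGrid:
    """Per-cell sensitivity/discrimination outcomes on an (N, tau) grid."""

    table: pd.DataFrame
    mode: str      # "deterministic" | "stochastic"
    alpha: float
    config: StochasticConfig


def phase_map(n_values, tau_values, alpha: float,
              config: StochasticConfig | None = None,
              mode: str = "deterministic", seed: int = 0) -> PhaseMapGrid:
    """Classify every (N, tau) cell as sensitive and/or discriminating.

    Deterministic mode evaluates the closed-form constraints
    (:func:`tcrpower.kp_model.sensitivity_ok` /
    :func:`~tcrpower.kp_model.discrimination_ok`) and permits fractional N;
    stochastic mode runs the two Gillespie scenarios per cell (integer N)
    and applies the same strict inequalities to the ensemble mean <CN>.
    Cells exactly at the threshold do not pass.
    """
    config = config or StochasticConfig()
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    lam = config.lambda_threshold
    delta_a = config.L_high ** (1.0 / alpha)
    rng = np.random.RandomState(seed)
    rows = []
    for n in n_values:
        for tau in tau_values:
            if tau <= 0:
                raise ValueError("tau must be > 0")
            kp = 1.0 / tau
            row = {"N": n, "tau": tau, "mode": mode, "alpha": alpha,
                   "mean_cn_sens": np.nan, "se_sens": np.nan,
                   "mean_cn_disc": np.nan, "se_disc": np.nan}
            if mode == "deterministic":
                row["sensitive"] = kp_model.sensitivity_ok(
                    n, kp, config.koff1, lam)
                row["discriminating"] = kp_model.discrimination_ok(
                    n, kp, config.koff1, lam, alpha,
                    L_high=config.L_high, R0=config.R0)
            else:
                if n != int(n):
                    raise ValueError("stochastic mode requires integer N")
                sens_sys = kp_model.KPSystem(
                    N=int(n), kp=kp, kon=config.kon, koff=config.koff1,
                    L0=1, R0=config.R0)
                m_s, se_s = ensemble_mean_cn(
                    sens_sys, config.n_realisations, config.t_end,
                    int(rng.randint(0, 2 ** 31 - 1)))
                disc_sys = kp_model.KPSystem(
                    N=int(n), kp=kp, kon=config.kon,
                    koff=delta_a * config.koff1,
                    L0=config.L_high, R0=config.R0)
                m_d, se_d = ensemble_mean_cn(
                    disc_sys, config.n_realisations, config.t_end,
                    int(rng.randint(0, 2 ** 31 - 1)))
                row.update(mean_cn_sens=m_s, se_sens=se_s,
                           mean_cn_disc=m_d, se_disc=se_d,
                           sensitive=bool(m_s > lam),
                           discriminating=bool(m_d < lam))
            rows.append(row)
    cols = ["N", "tau", "mean_cn_sens", "se_sens", "mean_cn_disc", "se_disc",
            "sensitive", "discriminating", "mode", "alpha"]
    return PhaseMapGrid(pd.DataFrame(rows)[cols], mode, alpha, config)


def deterministic_cn(sys: kp_model.KPSystem) -> float:
    """Deterministic steady-state CN for cross-checking stochastic means."""
    return kp_model.steady_state(sys)[1]
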