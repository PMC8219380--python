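"""Hierarchical fit of the KP potency model to multi-experiment data.

The model's log10 potency rho(N, kp_i, lambda_hat_i, gamma, delta_hat; KD)
is fitted to potency tables from I experiments simultaneously.  N, gamma
and delta_hat are global (shared across experiments); kp and lambda_hat
are local (one per experiment), giving 3 + 2*I parameters (27 for 12
experiments, 37 for 17).

The search is an annealed Metropolis-Hastings scheme: parameters start at
a draw from uniform priors (log10 scale for everything except N), each
proposal shifts every coordinate by Unif(-0.005, 0.005) times its prior
width (reflected at the bounds), and a candidate with larger summed
squared log10 residual D is still accepted with probability
exp(-(D_cand - D_curr)/xi).  The temperature xi starts at 10 and is
dropped along a fixed schedule each time the accepted distance first
reaches a threshold; a chain terminates when D falls below the
termination distance.  Running many independent chains (1000 in the full
protocol) maps the distribution of parameter sets compatible with the
data, from which the proofreading delay tau_KP = N/kp is derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .kp_model import DEFAULT_KON

# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior box on the fitting scale (linear for N, log10 otherwise).

    Vector layout: [N, log10(gamma), log10(delta_hat),
    log10(kp_1..I), log10(lambda_hat_1..I)].
    """

    lo: np.ndarray
    hi: np.ndarray
    n_experiments: int
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.lo >= self.hi):
            raise ValueError("prior lower bounds must be < upper bounds")

    @property
    def n_params(self) -> int:
        return len(self.lo)

    def sample(self, rng: np.random.RandomState) -> np.ndarray:
        return rng.uniform(self.lo, self.hi)


#: per-parameter (lo, hi) on the fitting scale for the two data settings
_PRIOR_BLOCKS = {
    "plate": {"N": (0.0, 4.0), "log10_kp": (-1.0, 1.0),
              "log10_lambda_hat": (-4.0, 1.0), "log10_gamma": (-6.0, -4.0),
              "log10_delta_hat": (-7.0, -5.0)},
    "cell": {"N": (0.0, 4.0), "log10_kp": (-1.0, 1.0),
             "log10_lambda_hat": (-6.0, -3.0), "log10_gamma": (-6.0, -4.0),
             "log10_delta_hat": (-7.0, -5.0)},
}


def make_priors(n_experiments: int, prior_set: str = "plate") -> PriorSpec:
    """Prior box for ``n_experiments`` experiments (3 + 2*I parameters)."""
    if prior_set not in _PRIOR_BLOCKS:
        raise ValueError(f"prior_set must be 'plate' or 'cell', got {prior_set!r}")
    if n_experiments < 1:
        raise ValueError("need >= 1 experiment")
    b = _PRIOR_BLOCKS[prior_set]
    lo = [b["N"][0], b["log10_gamma"][0], b["log10_delta_hat"][0]]
    hi = [b["N"][1], b["log10_gamma"][1], b["log10_delta_hat"][1]]
    names = ["N", "log10_gamma", "log10_delta_hat"]
    for i in range(n_experiments):
        lo.append(b["log10_kp"][0]); hi.append(b["log10_kp"][1])
        names.append(f"log10_kp_{i + 1}")
    for i in range(n_experiments):
        lo.append(b["log10_lambda_hat"][0]); hi.append(b["log10_lambda_hat"][1])
        names.append(f"log10_lambda_hat_{i + 1}")
    return PriorSpec(np.array(lo), np.array(hi), n_experiments, names)


# ---------------------------------------------------------------------------
# annealing schedule


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature ladder: xi drops to xis[k] when the accepted distance
    first reaches thresholds[k]; the chain stops when D < termination."""

    initial_xi: float
    thresholds: np.ndarray  # strictly decreasing
    xis: np.ndarray         # strictly decreasing
    termination: float
    max_steps: int = 5_000_000

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        x = np.asarray(self.xis, dtype=float)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "xis", x)
        if len(t) != len(x):
            raise ValueError("thresholds and xis must have equal length")
        if np.any(np.diff(t) >= 0) or np.any(np.diff(x) >= 0):
            raise ValueError("thresholds and xis must be strictly decreasing")
        if np.any(x >= self.initial_xi):
            raise ValueError("xis must be below initial_xi")
        if self.termination <= 0 or self.max_steps < 1:
            raise ValueError("termination and max_steps must be positive")


PLATE_SCHEDULE = AnnealSchedule(10.0, np.array([50.0, 30.0, 20.0, 18.0, 17.5]),
                                np.array([1.0, 0.1, 0.01, 0.005, 0.001]), 11.08)
CELL_SCHEDULE = AnnealSchedule(10.0, np.array([100.0, 75.0, 50.0, 40.0, 35.0]),
                               np.array([1.0, 0.1, 0.01, 0.005, 0.001]), 39.2)


def synthetic_schedule(n_points: int, sigma_log: float,
                       max_steps: int = 5_000_000) -> AnnealSchedule:
    """Annealing schedule for synthetic data of known noise level.

    Termination is set to n_points*sigma_log^2*1.2 (20% above the expected
    residual sum at the true parameters); the threshold ladder and the
    temperatures are the plate schedule rescaled to that distance scale.
    """
    term = max(n_points * sigma_log ** 2 * 1.2, 1e-12)
    factor = term / PLATE_SCHEDULE.termination
    return AnnealSchedule(10.0 * factor, PLATE_SCHEDULE.thresholds * factor,
                          PLATE_SCHEDULE.xis * factor, term, max_steps)


# ---------------------------------------------------------------------------
# data container


@dataclass(frozen=True)
class PotencyData:
    """Flattened multi-experiment potency observations.

    kd (uM), log10 potency and the 0-based experiment index of every
    included data point; built from a potency_table with
    :func:`potency_data_from_table`.
    """

    kd: np.ndarray
    log_potency: np.ndarray
    exp_idx: np.ndarray
    experiment_ids: list

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    @property
    def n_points(self) -> int:
        return len(self.kd)


def potency_data_from_table(table: pd.DataFrame) -> PotencyData:
    """Build :class:`PotencyData` from a potency_table DataFrame,
    dropping flagged rows (unreachable/extrapolated/...)."""
    df = table.copy()
    if "flag" in df.columns:
        df = df[df["flag"].fillna("").astype(str) == ""]
    df = df.dropna(subset=["kd_uM", "potency"])
    if df.empty:
        raise ValueError("no usable potency records")
    exp_ids = sorted(df["experiment_id"].unique())
    idx_of = {e: i for i, e in enumerate(exp_ids)}
    return PotencyData(df["kd_uM"].to_numpy(dtype=float),
                       np.log10(df["potency"].to_numpy(dtype=float)),
                       df["experiment_id"].map(idx_of).to_numpy(dtype=np.int64),
                       list(exp_ids))


# ---------------------------------------------------------------------------
# distance / perturbation / MH step (reference implementations)


@njit(cache=True)
def _distance_nb(theta, kd, logp, exp_idx, n_exp, kon):
    n = theta[0]
    gamma = 10.0 ** theta[1]
    delta_hat = 10.0 ** theta[2]
    d = 0.0
    for j in range(kd.size):
        e = exp_idx[j]
        kp = 10.0 ** theta[3 + e]
        lam_hat = 10.0 ** theta[3 + n_exp + e]
        one_plus = 1.0 + kon * kd[j] / kp
        big_b = one_plus ** n
        if lam_hat * gamma * big_b >= 1.0:
            return np.inf
        arg = 1.0 - delta_hat * kd[j] / (lam_hat * big_b - 1.0 / gamma)
        if arg <= 0.0:
            return np.inf
        rho = (math.log10(lam_hat) + n * math.log10(one_plus)
               + math.log10(arg))
        r = rho - logp[j]
        d += r * r
    return d


def distance(theta: np.ndarray, data: PotencyData,
             kon: float = DEFAULT_KON) -> float:
    """Summed squared log10 potency residual D(theta); +inf when the
    model's potency is undefined (unreachable ligand) at theta."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != 3 + 2 * data.n_experiments:
        raise ValueError("theta has wrong length for this data")
    return float(_distance_nb(theta, data.kd, data.log_potency,
                              data.exp_idx, data.n_experiments, kon))


def perturb(theta: np.ndarray, priors: PriorSpec,
            rng: np.random.RandomState) -> np.ndarray:
    """Propose a candidate: every coordinate shifted independently by
    Unif(-0.005, 0.005) times its prior width, reflected at the bounds.
    (For N with prior (0, 4) the shift range is +/-0.02.)"""
    width = priors.hi - priors.lo
    cand = np.empty_like(theta)
    for k in range(theta.size):
        c = theta[k] + rng.uniform(-0.005, 0.005) * width[k]
        if c > priors.hi[k]:
            c = 2.0 * priors.hi[k] - c
        if c < priors.lo[k]:
            c = 2.0 * priors.lo[k] - c
        cand[k] = c
    return cand


def mh_step(d_curr: float, d_cand: float, xi: float,
            rng: np.random.RandomState) -> bool:
    """Metropolis acceptance on distances: always accept improvements,
    otherwise accept with probability exp(-(d_cand - d_curr)/xi)."""
    if d_cand < d_curr:
        return True
    delta = d_cand - d_curr
    if not np.isfinite(delta):  # both infinite: treat as equal, accept
        return bool(np.isinf(d_curr) and np.isinf(d_cand))
    return bool(rng.random_sample() < math.exp(-delta / xi))


# ---------------------------------------------------------------------------
# chain kernels


@njit(cache=True)
def _chain_nb(theta0, lo, hi, kd, logp, exp_idx, n_exp, kon,
              xi0, thresholds, xis, termination, max_steps, seed):
    np.random.seed(seed)
    p = theta0.size
    width = hi - lo
    theta = theta0.copy()
    d = _distance_nb(theta, kd, logp, exp_idx, n_exp, kon)
    xi = xi0
    pos = 0
    while pos < thresholds.size and d <= thresholds[pos]:
        xi = xis[pos]
        pos += 1
    steps = 0
    cand = np.empty(p)
    while d >= termination and steps < max_steps:
        for k in range(p):
            c = theta[k] + np.random.uniform(-0.005, 0.005) * width[k]
            if c > hi[k]:
                c = 2.0 * hi[k] - c
            if c < lo[k]:
                c = 2.0 * lo[k] - c
            cand[k] = c
        dc = _distance_nb(cand, kd, logp, exp_idx, n_exp, kon)
        accept = dc < d
        if not accept:
            delta = dc - d
            if np.isinf(d) and np.isinf(dc):
                accept = True
            elif np.isfinite(delta):
                accept = np.random.random() < np.exp(-delta / xi)
        if accept:
            theta[:] = cand
            d = dc
            while pos < thresholds.size and d <= thresholds[pos]:
                xi = xis[pos]
                pos += 1
        steps += 1
    return theta, d, steps


def _chain_py(theta0, priors, data, kon, schedule, seed):
    rng = np.random.RandomState(seed)
    theta = theta0.copy()
    d = distance(theta, data, kon)
    xi = schedule.initial_xi
    pos = 0
    while pos < len(schedule.thresholds) and d <= schedule.thresholds[pos]:
        xi = schedule.xis[pos]
        pos += 1
    steps = 0
    while d >= schedule.termination and steps < schedule.max_steps:
        cand = perturb(theta, priors, rng)
        dc = distance(cand, data, kon)
        if dc < d:
            accept = True
        else:
            delta = dc - d
            if np.isinf(d) and np.isinf(dc):
                accept = True
            elif np.isfinite(delta):
                accept = rng.random_sample() < math.exp(-delta / xi)
            else:
                accept = False
        if accept:
            theta = cand
            d = dc
            while pos < len(schedule.thresholds) and d <= schedule.thresholds[pos]:
                xi = schedule.xis[pos]
                pos += 1
        steps += 1
    return theta, d, steps


@dataclass(frozen=True)
class ChainResult:
    theta: np.ndarray
    distance: float
    steps: int
    converged: bool


def run_chain(data: PotencyData, priors: PriorSpec, schedule: AnnealSchedule,
              seed: int, kon: float = DEFAULT_KON,
              engine: str = "numba") -> ChainResult:
    """Run one annealed MH chain to termination (or the max_steps safeguard).

    The initial parameter set is drawn from the priors; draws for which
    the distance is infinite (the model undefined for some data point)
    are redrawn, since the distance gives such a start no direction.
    Both engines consume the same RNG stream, so trajectories are
    identical between them for a given seed.
    """
    rng = np.random.RandomState(seed)
    theta0 = priors.sample(rng)
    for _ in range(1000):
        if np.isfinite(distance(theta0, data, kon)):
            break
        theta0 = priors.sample(rng)
    else:
        raise RuntimeError("could not find a finite-distance prior draw")
    chain_seed = int(rng.randint(0, 2 ** 31 - 1))
    if engine == "numba":
        theta, d, steps = _chain_nb(
            theta0, priors.lo, priors.hi, data.kd, data.log_potency,
            data.exp_idx, data.n_experiments, kon, schedule.initial_xi,
            schedule.thresholds, schedule.xis, schedule.termination,
            schedule.max_steps, chain_seed)
    elif engine == "python":
        theta, d, steps = _chain_py(theta0, priors, data, kon, schedule,
                                    chain_seed)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return ChainResult(np.asarray(theta), float(d), int(steps),
                       bool(d < schedule.termination))


# ---------------------------------------------------------------------------
# ensemble


@dataclass(frozen=True)
class FitEnsemble:
    """Converged final parameter sets of the independent chains."""

    table: pd.DataFrame       # one row per converged chain
    n_failed: int
    priors: PriorSpec
    schedule: AnnealSchedule

    def summary(self) -> dict:
        """Ensemble summaries: N as median (min-max), per-experiment kp
        medians, tau_KP = N/kp per chain and experiment, and pooled means
        with 95% percentile intervals across the ensemble."""
        t = self.table
        I = self.priors.n_experiments
        kp_cols = [f"kp_{i + 1}" for i in range(I)]
        kp_vals = t[kp_cols].to_numpy()
        tau_vals = t[["N"]].to_numpy() / kp_vals
        pooled_kp = kp_vals.ravel()
        pooled_tau = tau_vals.ravel()
        return {
            "n_chains": int(len(t)),
            "n_failed": int(self.n_failed),
            "N": {"median": float(t["N"].median()),
                  "min": float(t["N"].min()), "max": float(t["N"].max())},
            "kp": {"per_experiment_median": [float(np.median(kp_vals[:, i]))
                                             for i in range(I)],
                   "pooled_mean": float(np.mean(np.median(kp_vals, axis=0))),
                   "pooled_ci95": [float(np.percentile(pooled_kp, 2.5)),
                                   float(np.percentile(pooled_kp, 97.5))]},
            "tau_kp": {"per_experiment_median": [float(np.median(tau_vals[:, i]))
                                                 for i in range(I)],
                       "pooled_mean": float(np.mean(np.median(tau_vals, axis=0))),
                       "pooled_ci95": [float(np.percentile(pooled_tau, 2.5)),
                                       float(np.percentile(pooled_tau, 97.5))]},
            "distance": {"max": float(t["D"].max()),
                         "termination": float(self.schedule.termination)},
        }


def fit_ensemble(data: PotencyData, priors: PriorSpec,
                 schedule: AnnealSchedule, n_chains: int = 1000,
                 seed: int = 0, kon: float = DEFAULT_KON,
                 engine: str = "numba") -> FitEnsemble:
    """Run ``n_chains`` independent annealed MH chains with per-chain
    sub-seeds derived deterministically from ``seed``."""
    if priors.n_experiments != data.n_experiments:
        raise ValueError("priors sized for a different number of experiments")
    master = np.random.RandomState(seed)
    sub_seeds = master.randint(0, 2 ** 31 - 1, size=n_chains)
    rows = []
    n_failed = 0
    I = priors.n_experiments
    for c in range(n_chains):
        res = run_chain(data, priors, schedule, int(sub_seeds[c]), kon, engine)
        if not res.converged:
            n_failed += 1
            continue
        row = {"chain": c, "N": res.theta[0],
               "gamma": 10.0 ** res.theta[1],
               "delta_hat": 10.0 ** res.theta[2],
               "D": res.distance, "steps": res.steps}
        for i in range(I):
            row[f"kp_{i + 1}"] = 10.0 ** res.theta[3 + i]
            row[f"lambda_hat_{i + 1}"] = 10.0 ** res.theta[3 + I + i]
        rows.append(row)
    if not rows:
        raise RuntimeError("all chains failed to reach the termination distance")
    return FitEnsemble(pd.DataFrame(rows), n_failed, priors, schedule)
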