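"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes,
so that every fitter can be tested against known truth:

- SPR titrations: Langmuir steady-state curves B = Bmax*f_active*T/(KD+T)
  with additive Gaussian RU noise, plus W6/32 antibody traces whose
  plateau Rmax is constructed by inverting the standard curve
  Bmax_active = slope*Rmax + intercept, so that in the noiseless case the
  standard-curve machinery recovers truth exactly.  Only the fraction
  f_active of immobilised pMHC is correctly folded, which is why raw
  immobilisation level cannot replace the antibody proxy.
- KP potency tables: log10 potency = rho(N, kp_i, lambda_hat_i, gamma,
  delta_hat; KD) + Gaussian(0, sigma_log) per experiment and ligand, with
  lognormal noise because the fit distance is a sum of squared log10
  residuals.  Ligands whose threshold is unreachable are emitted flagged.
- Dose-response curves: four-parameter sigmoids whose EC50 is set so that
  interpolating at the configured threshold returns the input potency
  exactly in the noiseless case.

Default panels span ~3 uM to ~1500 uM across 8 ligands, the physiological
TCR/pMHC affinity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kp_model

DEFAULT_TCR_CONC = tuple(0.625 * 2 ** k for k in range(8))  # 0.625..80 uM
DEFAULT_KD_PANEL = tuple(float(k) for k in np.geomspace(3.0, 1500.0, 8).round(2))


@dataclass(frozen=True)
class SPRGroundTruth:
    """True parameters behind a synthetic SPR dataset."""

    kd_uM: dict                      # ligand_id -> true KD (uM)
    #: immobilised pMHC response scale (RU); a scalar, or a per-ligand dict
    #: emulating the immobilisation-level variation across chip surfaces
    bmax_true: float | dict = 1500.0
    f_active: float = 0.7            # correctly folded fraction of pMHC
    w632_slope: float = 2.0          # standard-curve slope (RU/RU)
    w632_intercept: float = 0.0      # standard-curve intercept (RU)
    w632_kt: float = 30.0            # antibody-trace nuisance timescale (s)
    sigma_ru: float = 2.0            # additive response noise SD (RU)
    tcr_conc_uM: tuple = DEFAULT_TCR_CONC
    trace_times_s: tuple = tuple(np.linspace(15.0, 600.0, 20))
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not self.kd_uM or any(v <= 0 for v in self.kd_uM.values()):
            raise ValueError("need at least one ligand with KD > 0")
        if not 0 < self.f_active <= 1:
            raise ValueError("f_active must be in (0, 1]")
        if self.sigma_ru < 0:
            raise ValueError("sigma_ru must be >= 0")
        T = np.asarray(self.tcr_conc_uM, dtype=float)
        if np.any(T <= 0) or np.any(np.diff(T) <= 0):
            raise ValueError("TCR concentrations must be positive, increasing")
        if isinstance(self.bmax_true, dict):
            if set(self.bmax_true) != set(self.kd_uM):
                raise ValueError("per-ligand bmax_true must cover all ligands")
            if any(v <= 0 for v in self.bmax_true.values()):
                raise ValueError("bmax_true values must be > 0")
        elif self.bmax_true <= 0:
            raise ValueError("bmax_true must be > 0")
        if self.w632_slope == 0:
            raise ValueError("w632_slope must be nonzero")

    def bmax_active(self, ligand: str) -> float:
        """TCR-visible Bmax (only folded pMHC binds TCR)."""
        b = (self.bmax_true[ligand] if isinstance(self.bmax_true, dict)
             else self.bmax_true)
        return b * self.f_active

    def rmax(self, ligand: str) -> float:
        """W6/32 plateau implied by inverting the standard curve."""
        return ((self.bmax_active(ligand) - self.w632_intercept)
                / self.w632_slope)

    def to_dict(self) -> dict:
        bmax = (dict(self.bmax_true) if isinstance(self.bmax_true, dict)
                else self.bmax_true)
        return {"kd_uM": dict(self.kd_uM), "bmax_true": bmax,
                "f_active": self.f_active, "w632_slope": self.w632_slope,
                "w632_intercept": self.w632_intercept, "w632_kt": self.w632_kt,
                "sigma_ru": self.sigma_ru,
                "tcr_conc_uM": list(self.tcr_conc_uM),
                "n_replicates": self.n_replicates}


def generate_spr_dataset(truth: SPRGroundTruth, seed: int
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw binding_curve and antibody_trace tables from the truth.

    Responses are Bmax_true*f_active*T/(KD+T) + N(0, sigma_ru); antibody
    traces are Rmax*t/(Kt+t) + N(0, sigma_ru) with Rmax chosen so the
    standard curve holds exactly before noise.
    """
    rng = np.random.RandomState(seed)
    T = np.asarray(truth.tcr_conc_uM, dtype=float)
    t_trace = np.asarray(truth.trace_times_s, dtype=float)
    bind_rows, trace_rows = [], []
    for ligand, kd in truth.kd_uM.items():
        for rep in range(1, truth.n_replicates + 1):
            b = truth.bmax_active(ligand) * T / (kd + T)
            b = b + rng.normal(0.0, truth.sigma_ru, size=T.size) \
                if truth.sigma_ru > 0 else b
            for tc, resp in zip(T, b):
                bind_rows.append({"ligand_id": ligand, "tcr_conc_uM": tc,
                                  "response_RU": resp,
                                  "replicate_id": str(rep)})
        r = truth.rmax(ligand) * t_trace / (truth.w632_kt + t_trace)
        r = r + rng.normal(0.0, truth.sigma_ru, size=t_trace.size) \
            if truth.sigma_ru > 0 else r
        for ts, resp in zip(t_trace, r):
            trace_rows.append({"ligand_id": ligand, "time_s": ts,
                               "response_RU": resp})
    return (pd.DataFrame(bind_rows), pd.DataFrame(trace_rows),
            truth.to_dict())


def default_spr_truth(kd_uM: dict, seed: int = 0, sigma_ru: float = 2.0,
                      n_replicates: int = 3) -> SPRGroundTruth:
    """Study-condition SPR truth: per-ligand immobilisation levels drawn
    log-uniformly over 800-2000 RU (typical chip-to-chip variation)."""
    rng = np.random.RandomState(seed)
    levels = {lig: float(10.0 ** rng.uniform(np.log10(800.0), np.log10(2000.0)))
              for lig in kd_uM}
    return SPRGroundTruth(kd_uM=dict(kd_uM), bmax_true=levels,
                          sigma_ru=sigma_ru, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# KP potency tables


@dataclass(frozen=True)
class KPGroundTruth:
    """True parameters behind a synthetic multi-experiment potency table."""

    N: float = 2.67
    gamma: float = 1e-5
    delta_hat: float = 1e-6
    kp: tuple = (1.0,)               # per-experiment KP rate (s^-1)
    lambda_hat: tuple = (0.0316,)    # per-experiment threshold constant
    kon: float = kp_model.DEFAULT_KON
    kd_panels: tuple = None          # per-experiment KD panels (uM)
    sigma_log: float = 0.1           # lognormal potency noise SD (log10)

    def __post_init__(self) -> None:
        if self.N < 0 or self.gamma <= 0 or self.delta_hat <= 0:
            raise ValueError("N must be >= 0; gamma, delta_hat > 0")
        if len(self.kp) != len(self.lambda_hat):
            raise ValueError("kp and lambda_hat must have one entry per experiment")
        if any(k <= 0 for k in self.kp) or any(l <= 0 for l in self.lambda_hat):
            raise ValueError("kp and lambda_hat must be > 0")
        if self.sigma_log < 0 or self.kon <= 0:
            raise ValueError("sigma_log >= 0 and kon > 0 required")
        panels = self.kd_panels
        if panels is None:
            panels = tuple(DEFAULT_KD_PANEL for _ in self.kp)
        panels = tuple(tuple(float(k) for k in p) for p in panels)
        if len(panels) != len(self.kp):
            raise ValueError("need one KD panel per experiment")
        for p in panels:
            if any(k <= 0 for k in p):
                raise ValueError("KD values must be > 0")
        object.__setattr__(self, "kd_panels", panels)

    @property
    def n_experiments(self) -> int:
        return len(self.kp)

    def to_dict(self) -> dict:
        return {"N": self.N, "gamma": self.gamma, "delta_hat": self.delta_hat,
                "kp": list(self.kp), "lambda_hat": list(self.lambda_hat),
                "kon": self.kon,
                "kd_panels": [list(p) for p in self.kd_panels],
                "sigma_log": self.sigma_log}


def default_kp_truth(n_experiments: int, seed: int = 0,
                     sigma_log: float = 0.1,
                     prior_set: str = "plate") -> KPGroundTruth:
    """Study-condition truth: N = 2.67, mid-prior global constants, and
    per-experiment kp / lambda_hat drawn from the central half of the
    priors, over the default 3-1500 uM KD panel."""
    rng = np.random.RandomState(seed)
    lam_lo, lam_hi = (-4.0, 1.0) if prior_set == "plate" else (-6.0, -3.0)
    lam_mid, lam_w = 0.5 * (lam_lo + lam_hi), lam_hi - lam_lo
    kp = 10.0 ** rng.uniform(-0.25, 0.25, size=n_experiments)
    lam = 10.0 ** rng.uniform(lam_mid - 0.25 * lam_w, lam_mid + 0.25 * lam_w,
                              size=n_experiments)
    return KPGroundTruth(N=2.67, gamma=1e-5, delta_hat=1e-6,
                         kp=tuple(kp), lambda_hat=tuple(lam),
                         sigma_log=sigma_log)


def generate_kp_potency_dataset(truth: KPGroundTruth, seed: int
                                ) -> tuple[pd.DataFrame, dict]:
    """Draw a potency_table from the KP potency expression.

    log10 potency = rho(...) + N(0, sigma_log); ligands for which the
    threshold is unreachable are emitted with an "unreachable" flag and
    empty potency.
    """
    rng = np.random.RandomState(seed)
    rows = []
    for i in range(truth.n_experiments):
        exp_id = f"E{i + 1:02d}"
        kds = np.asarray(truth.kd_panels[i], dtype=float)
        rho = kp_model.log_potency_rho(truth.N, truth.kp[i],
                                       truth.lambda_hat[i], truth.gamma,
                                       truth.delta_hat, kds, truth.kon)
        noise = rng.normal(0.0, truth.sigma_log, size=kds.size) \
            if truth.sigma_log > 0 else np.zeros(kds.size)
        for j, kd in enumerate(kds):
            if np.isnan(rho[j]):
                rows.append({"study_id": "synthetic", "experiment_id": exp_id,
                             "ligand_id": f"L{j + 1:02d}", "kd_uM": kd,
                             "potency": np.nan, "readout": "CD69",
                             "flag": "unreachable"})
            else:
                rows.append({"study_id": "synthetic", "experiment_id": exp_id,
                             "ligand_id": f"L{j + 1:02d}", "kd_uM": kd,
                             "potency": 10.0 ** (rho[j] + noise[j]),
                             "readout": "CD69", "flag": ""})
    return pd.DataFrame(rows), truth.to_dict()


# ---------------------------------------------------------------------------
# dose-response curves


def generate_dose_response_dataset(potency_table: pd.DataFrame,
                                   hill_shape: tuple = (0.0, 60.0, 1.0),
                                   doses=None,
                                   threshold_percent: float = 15.0,
                                   sigma_percent: float = 0.0,
                                   seed: int = 0) -> pd.DataFrame:
    """Invert potencies into four-parameter sigmoid dose-response curves.

    For each unflagged record the EC50 is set so that interpolating the
    noiseless curve at ``threshold_percent`` returns the input potency
    exactly: EC50 = P * ((Emax-Emin)/(X-Emin) - 1)^(1/H).  Ligands whose
    potency exceeds the dose range are still emitted (they exercise the
    downstream no-extrapolation rule).
    """
    emin, emax, hill = hill_shape
    if not emin < threshold_percent < emax:
        raise ValueError("need Emin < threshold_percent < Emax so PX exists")
    if hill <= 0:
        raise ValueError("Hill coefficient must be > 0")
    if doses is None:
        doses = np.geomspace(1e-3, 1e3, 13)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.RandomState(seed)
    ratio = (emax - emin) / (threshold_percent - emin) - 1.0
    rows = []
    usable = potency_table
    if "flag" in usable.columns:
        usable = usable[usable["flag"].fillna("").astype(str) == ""]
    for _, rec in usable.iterrows():
        p = float(rec["potency"])
        ec50 = p * ratio ** (1.0 / hill)
        resp = emin + (emax - emin) / (1.0 + (ec50 / doses) ** hill)
        if sigma_percent > 0:
            resp = resp + rng.normal(0.0, sigma_percent, size=doses.size)
        for d, r in zip(doses, resp):
            rows.append({"experiment_id": rec["experiment_id"],
                         "ligand_id": rec["ligand_id"], "dose": d,
                         "response_percent": r})
    if not rows:
        raise ValueError("no unflagged potency records to invert")
    return pd.DataFrame(rows)
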