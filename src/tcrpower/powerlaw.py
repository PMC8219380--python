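"""The power-law discrimination statistic.

Ligand potency and affinity obey an empirical power law
P = 10^C * KD^alpha, fitted as ordinary least squares in log-log space:
log10(P) = C + alpha*log10(KD).  The slope alpha is the discrimination
power — the factor by which affinity changes are amplified into potency
changes (alpha = 1 is the receptor-occupancy baseline, no amplification) —
and the intercept C is the sensitivity, the log10 potency of a reference
KD = 1 uM ligand.  alpha is dimensionless and unit-invariant; C is not.

Inclusion rules applied before fitting: records with KD < 1 uM are dropped
(potency saturates in that regime, which would flatten the slope) and
flagged records (extrapolated / below-threshold / unreachable potencies)
are dropped, each logged with the rule that fired.  When kon varies across
ligands the affinity axis should be koff instead of KD; the axis is always
an explicit choice, never automatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float           # slope, the discrimination power
    C: float               # intercept, log10 potency at affinity = 1
    r_squared: float
    p_slope: float         # H0: alpha = 0
    alpha_ci: tuple        # 95% CI for alpha
    n_points: int
    affinity_axis: str     # "KD" | "koff"


def fit_power_law(records: pd.DataFrame,
                  affinity_axis: str = "KD") -> PowerLawFit:
    """OLS of log10(potency) on log10(affinity).

    ``records`` needs a ``potency`` column and ``kd_uM`` (axis "KD") or
    ``koff_per_s`` (axis "koff").  Flagged rows must already have been
    removed (see :func:`apply_inclusion_rules`).
    """
    col = {"KD": "kd_uM", "koff": "koff_per_s"}.get(affinity_axis)
    if col is None:
        raise ValueError(f"affinity_axis must be 'KD' or 'koff', got {affinity_axis!r}")
    if col not in records.columns:
        raise ValueError(f"records lack the '{col}' column for axis {affinity_axis}")
    sub = records.dropna(subset=[col, "potency"])
    x = np.log10(sub[col].to_numpy(dtype=float))
    y = np.log10(sub["potency"].to_numpy(dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError(f"insufficient points for regression (n={n} < 3)")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in affinity")
    ols = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (ols.slope - tcrit * ols.stderr, ols.slope + tcrit * ols.stderr)
    return PowerLawFit(float(ols.slope), float(ols.intercept),
                       float(ols.rvalue ** 2), float(ols.pvalue),
                       (float(ci[0]), float(ci[1])), n, affinity_axis)


def apply_inclusion_rules(records: pd.DataFrame,
                          kd_exclusion_floor: float = 1.0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop saturation-regime and flagged records; return (kept, audit log).

    Rules: ``kd_below_floor`` removes KD < ``kd_exclusion_floor`` uM (the
    engineered high-affinity saturation regime); ``flagged:<reason>``
    removes records whose potency was excluded upstream.  The audit log
    lists every dropped record with the rule that fired.
    """
    audit_rows = []
    keep = np.ones(len(records), dtype=bool)
    flags = (records["flag"].fillna("").astype(str)
             if "flag" in records.columns else pd.Series("", index=records.index))
    for pos, (idx, row) in enumerate(records.iterrows()):
        if flags.loc[idx] != "":
            keep[pos] = False
            audit_rows.append({"ligand_id": row.get("ligand_id", ""),
                               "experiment_id": row.get("experiment_id", ""),
                               "rule": f"flagged:{flags.loc[idx]}"})
        elif "kd_uM" in records.columns and pd.notna(row.get("kd_uM")) \
                and float(row["kd_uM"]) < kd_exclusion_floor:
            keep[pos] = False
            audit_rows.append({"ligand_id": row.get("ligand_id", ""),
                               "experiment_id": row.get("experiment_id", ""),
                               "rule": "kd_below_floor"})
    audit = pd.DataFrame(audit_rows, columns=["ligand_id", "experiment_id", "rule"])
    return records.loc[keep].copy(), audit


def fold_amplification(fold_kd: float, alpha: float) -> float:
    """Fold-change in potency compensating a fold-change in affinity.

    Under the power law, a ``fold_kd``-fold affinity loss requires a
    ``fold_kd**alpha``-fold dose increase: 25-fold at alpha=2 for a 5-fold
    affinity loss, but ~2 million-fold at the near-perfect alpha=9.
    """
    if fold_kd <= 0:
        raise ValueError("fold_kd must be > 0")
    return float(fold_kd ** alpha)


def aggregate_alpha(fits: list[PowerLawFit], significance_alpha: float = 0.05,
                    include_nonsignificant: bool = False
                    ) -> tuple[float, tuple, int]:
    """Mean discrimination power across fits with a t-based 95% CI.

    Fits whose slope p-value is >= ``significance_alpha`` are dropped
    unless ``include_nonsignificant`` (the explicit override used for the
    sparse original-mouse datasets).  Returns (mean, (lo, hi), n_included).
    """
    if not fits:
        raise ValueError("need >= 1 fit")
    kept = [f for f in fits
            if include_nonsignificant or f.p_slope < significance_alpha]
    if not kept:
        raise ValueError("no significant fits to aggregate "
                         "(and include_nonsignificant is off)")
    alphas = np.array([f.alpha for f in kept])
    mean = float(alphas.mean())
    if len(alphas) > 1:
        sem = alphas.std(ddof=1) / np.sqrt(len(alphas))
        tcrit = stats.t.ppf(0.975, len(alphas) - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        ci = (np.nan, np.nan)
    return mean, (float(ci[0]), float(ci[1])), len(kept)


def test_alpha_vs_one(alphas) -> tuple[float, float]:
    """Two-sided one-sample t-test of discrimination powers against 1.

    Performed on log10-transformed values (H0: log10 alpha = 0), matching
    the convention that statistics on discrimination powers are computed
    on the log scale.  Returns (t statistic, p-value).
    """
    arr = np.asarray(alphas, dtype=float)
    if len(arr) < 2:
        raise ValueError("need >= 2 values")
    if np.any(arr <= 0):
        raise ValueError("alphas must be > 0 for the log transform")
    logs = np.log10(arr)
    if np.ptp(logs) == 0:
        if np.all(logs == 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance in alphas")
    res = stats.ttest_1samp(logs, 0.0)
    return float(res.statistic), float(res.pvalue)
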