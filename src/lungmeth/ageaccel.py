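"""Linear epigenetic-clock application and age-acceleration association.

A clock is an intercept plus per-CpG weights applied to beta values
(``age = intercept + sum_i coef_i * beta_i``).  Age acceleration is the
residual of clock-predicted age regressed on chronological age — by
construction uncorrelated with chronological age — and its association with
a lung-function outcome is estimated with an ordinary linear model adjusting
for covariates.  Clock coefficients are user-supplied; no published clock is
bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ewas as _ewas

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClockModel:
    """Linear clock: predicted age (years) = intercept + coefficients . beta."""

    intercept: float
    coefficients: pd.Series  # index: cpg_id, values: years per beta unit

    def __post_init__(self):
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate CpGs in clock coefficients")
        if not np.isfinite(self.coefficients.to_numpy()).all() or not np.isfinite(self.intercept):
            raise ValueError("clock weights must be finite")


def read_clock(path) -> ClockModel:
    """Read a clock TSV (columns cpg_id, coefficient; one 'intercept' row)."""
    tab = pd.read_csv(path, sep="\t")
    inter = tab[tab["cpg_id"] == "intercept"]
    intercept = float(inter["coefficient"].iloc[0]) if len(inter) else 0.0
    coefs = tab[tab["cpg_id"] != "intercept"].set_index("cpg_id")["coefficient"].astype(float)
    return ClockModel(intercept=intercept, coefficients=coefs)


def write_clock(clock: ClockModel, path) -> None:
    tab = pd.concat(
        [
            pd.DataFrame({"cpg_id": ["intercept"], "coefficient": [clock.intercept]}),
            clock.coefficients.rename("coefficient").rename_axis("cpg_id").reset_index(),
        ]
    )
    tab.to_csv(path, sep="\t", index=False)


def predict_age(
    beta: pd.DataFrame,
    clock: ClockModel,
    missing_policy: str = "mean",
    min_coverage: float = 0.5,
) -> pd.Series:
    """Apply a linear clock to a beta matrix (CpG x sample).

    Clock CpGs absent from the matrix are imputed at the cohort mean beta of
    the available clock CpGs (``missing_policy='mean'``) or raise
    (``'strict'``).  Coverage below ``min_coverage`` always raises, listing
    the missing CpGs.
    """
    if missing_policy not in ("mean", "strict"):
        raise ValueError("missing_policy must be 'mean' or 'strict'")
    clock_cpgs = clock.coefficients.index
    present = [c for c in clock_cpgs if c in beta.index]
    missing = [c for c in clock_cpgs if c not in beta.index]
    coverage = len(present) / len(clock_cpgs) if len(clock_cpgs) else 1.0
    if coverage < min_coverage:
        raise ValueError(
            f"clock coverage {coverage:.2f} below floor {min_coverage}; "
            f"missing CpGs: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    if missing and missing_policy == "strict":
        raise ValueError(f"{len(missing)} clock CpG(s) absent under strict policy: {missing[:10]}")
    pred = pd.Series(clock.intercept, index=beta.columns, dtype=float)
    if present:
        sub = beta.loc[present]
        filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        pred = pred + clock.coefficients.loc[present] @ filled
    if missing:
        # cohort-mean imputation: each missing clock CpG contributes its
        # coefficient times the mean beta of the measured clock CpGs
        mean_beta = float(np.nanmean(beta.loc[present].to_numpy())) if present else 0.5
        pred = pred + clock.coefficients.loc[missing].sum() * mean_beta
        logger.info("predict_age: imputed %d missing clock CpG(s) at mean beta", len(missing))
    return pred.rename("predicted_age")


def age_acceleration(predicted: pd.Series, chronological: pd.Series) -> pd.Series:
    """Residual age acceleration: predicted age regressed on chronological age.

    With constant chronological age the regression is degenerate and the
    acceleration falls back to ``predicted - mean(predicted)`` (logged).
    """
    pred, chron = predicted.align(chronological, join="inner")
    if len(pred) == 0:
        raise ValueError("no overlapping samples")
    y = pred.to_numpy(dtype=float)
    x = chron.to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        logger.warning("age_acceleration: constant chronological age; centring predicted age")
        return pd.Series(y - np.nanmean(y), index=pred.index, name="age_accel")
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ coef, index=pred.index, name="age_accel")


def associate_acceleration(
    acceleration: pd.Series,
    samples: pd.DataFrame,
    outcome: str,
    covariates: list[str],
) -> dict:
    """Linear model ``outcome ~ acceleration + covariates``.

    Returns a dict with the acceleration coefficient, its SE, p-value and n.
    """
    sub = samples.set_index("sample_id")
    common = [s for s in acceleration.index if s in sub.index]
    if not common:
        raise ValueError("no samples shared between acceleration vector and sample table")
    sub = sub.loc[common].reset_index()
    accel = acceleration.loc[common].to_numpy(dtype=float)
    if np.nanstd(accel) == 0:
        raise ValueError("zero-variance acceleration; association not identifiable")
    keep = sub[outcome].notna().to_numpy() & ~np.isnan(accel)
    for cov in covariates:
        keep &= sub[cov].notna().to_numpy()
    sub, accel = sub[keep], accel[keep]
    Xc, names = _ewas.build_design(sub, covariates)
    X = np.column_stack([Xc, accel])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise _ewas.RankDeficientError("acceleration collinear with covariates")
    fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
    j = X.shape[1] - 1
    return {
        "outcome": outcome,
        "effect": float(fit.params[j]),
        "se": float(fit.bse[j]),
        "p": float(fit.pvalues[j]),
        "n": int(len(sub)),
    }


def synthetic_clock_from_cohort(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    n_cpgs: int = 50,
    seed: int = 0,
) -> ClockModel:
    """Construct a synthetic linear clock from a cohort's own data.

    Least-squares fit of chronological age on ``n_cpgs`` randomly chosen CpGs'
    beta values — a stand-in used by the simulated pipeline so the
    age-acceleration stage is exercised end to end; it is not a published
    clock and has no biological meaning outside the simulation.
    """
    rng = np.random.default_rng(seed)
    pick = rng.choice(beta.index.to_numpy(), size=min(n_cpgs, len(beta.index)), replace=False)
    sub = beta.loc[pick, samples["sample_id"]].to_numpy().T
    age = samples["age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(age)), sub])
    coef, *_ = np.linalg.lstsq(X, age, rcond=None)
    return ClockModel(intercept=float(coef[0]), coefficients=pd.Series(coef[1:], index=pick))
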