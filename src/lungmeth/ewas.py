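"""Per-cohort robust-regression EWAS of lung-function outcomes on M-values.

Each CpG is analysed with a multivariable M-estimator: the outcome is
regressed on the CpG's M-values plus covariates using iteratively reweighted
least squares with the Tukey bisquare psi function (tuning constant 4.685,
~95% efficiency at the Gaussian), residual scale fixed at 1.4826 x MAD of the
initial least-squares residuals, and Huber sandwich standard errors.  Scans
are vectorised across CpGs: the covariate block of the design matrix is
shared and only the CpG-specific column(s) differ, so the whole scan runs as
batched linear algebra.

False-discovery control is Benjamini-Hochberg, computed within one scan
(one outcome x stratum x cohort family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from . import methio

logger = logging.getLogger(__name__)

#: Tukey bisquare tuning constant (~95% Gaussian efficiency)
TUKEY_C = 4.685
MAX_ITER = 50
COEF_TOL = 1e-8
#: MAD -> sigma consistency factor for the Gaussian
MAD_SCALE = 1.4826

#: per-CpG fits are skipped when complete cases fall below n_covariates + this
DF_GUARD = 10

EWAS_COLUMNS = ["cpg_id", "outcome", "cohort", "stratum", "n", "effect", "se", "p", "fdr"]


class RankDeficientError(ValueError):
    """The design matrix does not have full column rank."""


@dataclass
class RobustFit:
    """Result of a single robust regression fit."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    scale: float
    n_iter: int


# ---------------------------------------------------------------------------
# batched IRLS core
# ---------------------------------------------------------------------------

def _bisquare_weights(t: np.ndarray, c: float = TUKEY_C) -> np.ndarray:
    """w(t) = (1 - (t/c)^2)^2 inside |t| < c, else 0 (t = standardised residual)."""
    u = t / c
    inside = np.abs(u) < 1.0
    return np.where(inside, (1.0 - u * u) ** 2, 0.0)


def _psi(t: np.ndarray, c: float = TUKEY_C) -> np.ndarray:
    u = t / c
    inside = np.abs(u) < 1.0
    return np.where(inside, t * (1.0 - u * u) ** 2, 0.0)


def _psi_prime(t: np.ndarray, c: float = TUKEY_C) -> np.ndarray:
    u = (t / c) ** 2
    inside = u < 1.0
    return np.where(inside, (1.0 - u) * (1.0 - 5.0 * u), 0.0)


def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted least squares: X (K,n,p), y (K,n), w (K,n) -> beta (K,p)."""
    Xt = X.transpose(0, 2, 1)
    A = np.matmul(Xt * w[:, None, :], X)
    b = np.matmul(Xt, (w * y)[:, :, None])[:, :, 0]
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        bad = [k for k in range(A.shape[0]) if np.linalg.matrix_rank(A[k]) < A.shape[1]]
        raise RankDeficientError(
            f"singular weighted design for batch item(s) {bad[:5]}"
        ) from err


def robust_scan(
    X: np.ndarray,
    y: np.ndarray,
    obs_weights: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = COEF_TOL,
    c: float = TUKEY_C,
) -> dict:
    """Fit ``K`` robust regressions sharing the response ``y``.

    Parameters
    ----------
    X : ndarray (K, n, p)
        Batched design matrices (intercept included by the caller).
    y : ndarray (n,) or (K, n)
        Response; per-batch responses allowed.
    obs_weights : ndarray (K, n), optional
        0/1 inclusion mask implementing per-CpG complete-case analysis.

    Returns a dict with ``coef (K,p)``, ``se``, ``p``, ``converged (K,)``,
    ``scale (K,)``, ``n_iter`` and ``n_obs (K,)``.
    """
    X = np.asarray(X, dtype=float)
    K, n, p = X.shape
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = np.broadcast_to(y, (K, n))
    base = np.ones((K, n)) if obs_weights is None else np.asarray(obs_weights, dtype=float)
    n_obs = base.sum(axis=1)
    if np.any(n_obs < p):
        raise ValueError("fewer observations than parameters in at least one batch item")

    y0 = np.where(base > 0, y, 0.0)
    beta = _wls_solve(X, y0, base)
    resid = (y0 - np.matmul(X, beta[:, :, None])[:, :, 0]) * base

    # fixed residual scale: MAD of the initial LS residuals (consistency-scaled)
    if obs_weights is None:
        scale = MAD_SCALE * np.median(np.abs(resid), axis=1)
    else:
        abs_res = np.where(base > 0, np.abs(resid), np.nan)
        scale = MAD_SCALE * np.nanmedian(abs_res, axis=1)
    scale = np.maximum(scale, 1e-12)

    # iterate only the still-active (unconverged) batch items
    converged = np.zeros(K, dtype=bool)
    active = np.arange(K)
    it = 0
    for it in range(1, max_iter + 1):
        Xa, ya, ba = X[active], y0[active], base[active]
        t = resid[active] / scale[active, None]
        w = ba * _bisquare_weights(t, c)
        # guard: if bisquare downweights everything (can happen with degenerate
        # scale), fall back to the inclusion mask for that item
        dead = w.sum(axis=1) < p
        if dead.any():
            w[dead] = ba[dead]
        beta_new = _wls_solve(Xa, ya, w)
        delta = np.max(np.abs(beta_new - beta[active]), axis=1)
        beta[active] = beta_new
        resid[active] = (ya - np.matmul(Xa, beta_new[:, :, None])[:, :, 0]) * ba
        done = delta < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    converged[active] = False

    # Huber sandwich covariance with HC3-style leverage correction and a
    # small-sample df correction:
    #   A = sum psi'(r/s) x x' / s     B = sum psi(r/s)^2 / (1-h)^2 x x'
    #   cov = A^-1 B A^-1 * n/(n-p)
    # The leverage correction keeps the normal-approximation tail calibrated
    # when predictors are skewed (methylation M-values routinely are).
    t = resid / scale[:, None]
    psi_v = _psi(t, c) * base
    psip_v = _psi_prime(t, c) * base
    Xt = X.transpose(0, 2, 1)
    w_fin = base * _bisquare_weights(t, c)
    Aw = np.matmul(Xt * w_fin[:, None, :], X)
    try:
        Aw_inv = np.linalg.inv(Aw)
    except np.linalg.LinAlgError:
        Aw_inv = np.linalg.pinv(Aw + 1e-10 * np.eye(p)[None, :, :])
    hat = np.einsum("kni,kij,knj->kn", X, Aw_inv, X, optimize=True) * w_fin
    hat = np.clip(hat, 0.0, 0.99)
    A = np.matmul(Xt * (psip_v / scale[:, None])[:, None, :], X)
    B = np.matmul(Xt * (psi_v**2 / (1.0 - hat) ** 2)[:, None, :], X)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        # pathological items: perturb towards identity so the rest of the batch
        # survives; affected items are flagged unconverged with NaN SEs below
        ridge = A + 1e-10 * np.eye(p)[None, :, :]
        Ainv = np.linalg.pinv(ridge)
    cov = Ainv @ B @ np.transpose(Ainv, (0, 2, 1))
    dof = np.maximum(n_obs - p, 1.0)
    cov = cov * (n_obs / dof)[:, None, None]
    var = np.einsum("kii->ki", cov)
    bad_var = var <= 0
    if bad_var.any():
        converged = converged & ~bad_var.any(axis=1)
        var = np.where(bad_var, np.nan, var)
    se = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    # Satterthwaite effective degrees of freedom per coefficient
    # (Bell-McCaffrey style): the sandwich variance of coefficient j is a
    # weighted sum over observations with weights a_ij = [(A^-1 x_i)_j]^2;
    # df_j = (sum a)^2 / sum a^2.  High-leverage predictors (skewed M-values)
    # make the variance estimate noisy, so reference t_df rather than the
    # normal keeps genome-wide tails calibrated.
    D = np.matmul(Ainv, Xt)  # (K, p, n)
    a = (D * base[:, None, :]) ** 2
    s1 = a.sum(axis=2)
    s2 = (a * a).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        eff_df = np.where(s2 > 0, s1 * s1 / s2, dof[:, None])
    eff_df = np.clip(eff_df, 2.0, dof[:, None])
    pvals = 2.0 * stats.t.sf(np.abs(z), eff_df)
    # exact fits: zero residual scale makes z blow up; p underflows to 0 -> clip
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return {
        "coef": beta,
        "se": se,
        "p": pvals,
        "converged": converged,
        "scale": scale,
        "n_iter": it,
        "n_obs": n_obs,
        "eff_df": eff_df,
    }


def robust_fit(y: np.ndarray, X: np.ndarray) -> RobustFit:
    """Robust regression of ``y`` on design ``X`` (n, p), intercept included.

    Raises :class:`RankDeficientError` naming collinear columns when the
    design is singular; non-convergence is flagged on the result rather than
    raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (n, p)")
    n, p = X.shape
    if len(y) != n:
        raise ValueError("length of y must match rows of X")
    if n < p + 5:
        raise ValueError(f"need at least p+5={p + 5} observations, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns involved via the QR diagonal
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        collinear = [int(j) for j in np.where(diag < 1e-10 * diag.max())[0]]
        raise RankDeficientError(f"design matrix rank {rank} < {p}; suspect column(s) {collinear}")
    out = robust_scan(X[None, :, :], y)
    if not out["converged"][0]:
        logger.warning("robust_fit did not converge within %d iterations", MAX_ITER)
    return RobustFit(
        coef=out["coef"][0],
        se=out["se"][0],
        p=out["p"][0],
        converged=bool(out["converged"][0]),
        scale=float(out["scale"][0]),
        n_iter=out["n_iter"],
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (empty in, empty out)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q = fdrcorrection(p, alpha=0.05, method="indep")
    return q


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariate matrix; ``sex`` becomes a male indicator.

    Raises :class:`RankDeficientError` naming the collinear columns (e.g. a
    full set of cell proportions alongside the intercept).
    """
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            raise methio.SchemaError(f"covariate column '{cov}' not in sample table")
        if cov == "sex":
            cols.append((samples["sex"].to_numpy() == "M").astype(float))
            names.append("sex_male")
        else:
            vals = pd.to_numeric(samples[cov], errors="raise").to_numpy(dtype=float)
            cols.append(vals)
            names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        bad = [names[j] for j in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise RankDeficientError(f"collinear covariate column(s): {bad or names}")
    return X, names


def _subset_stratum(samples: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return samples
    if stratum not in ("F", "M"):
        raise ValueError("stratum must be one of 'all', 'F', 'M'")
    sub = samples[samples["sex"] == stratum]
    if len(sub) == 0:
        raise ValueError(f"stratum '{stratum}' is empty for this cohort")
    return sub


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def run_ewas(
    meth: pd.DataFrame,
    samples: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    stratum: str = "all",
    cohort_id: str | None = None,
    annotation: pd.DataFrame | None = None,
    min_n: int = 20,
) -> pd.DataFrame:
    """Scan every CpG (rows of the M-value matrix) against one outcome.

    Per-CpG complete-case analysis: samples missing the outcome or any
    covariate are dropped globally; samples missing a given CpG are dropped
    for that CpG only.  CpGs with fewer than ``n_covariates + 10`` complete
    cases are skipped (logged), as are all-missing CpGs.  When an annotation
    is supplied, sex-chromosome CpGs are only analysed within sex strata.

    Returns a DataFrame with columns ``cpg_id, outcome, cohort, stratum, n,
    effect, se, p, fdr`` plus a ``converged`` flag, one row per analysed CpG.
    """
    if outcome not in samples.columns:
        raise methio.SchemaError(f"outcome column '{outcome}' not in sample table")
    sub = _subset_stratum(samples, stratum)
    # align samples to matrix columns
    common = [s for s in meth.columns if s in set(sub["sample_id"])]
    sub = sub.set_index("sample_id").loc[common].reset_index()
    if len(sub) < min_n:
        raise ValueError(
            f"only {len(sub)} samples in stratum '{stratum}' after matching; minimum is {min_n}"
        )
    complete = sub[outcome].notna()
    for cov in covariates:
        if cov in sub.columns:
            complete &= sub[cov].notna()
    sub = sub[complete.to_numpy()]
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} complete-case samples; minimum is {min_n}")

    mat = meth[sub["sample_id"]]
    if annotation is not None and stratum == "all":
        ann = annotation.set_index("cpg_id")
        on_sex = [
            c for c in mat.index if c in ann.index and str(ann.at[c, "chrom"]) in methio.SEX_CHROMOSOMES
        ]
        if on_sex:
            logger.info(
                "run_ewas: excluding %d sex-chromosome CpG(s) from the combined stratum", len(on_sex)
            )
            mat = mat.drop(index=on_sex)

    y = sub[outcome].to_numpy(dtype=float)
    Xc, names = build_design(sub, covariates)
    q = Xc.shape[1]

    M = mat.to_numpy(dtype=float)  # (K, n)
    K, n = M.shape
    present = ~np.isnan(M)
    n_k = present.sum(axis=1)
    fit_mask = n_k >= (len(covariates) + DF_GUARD)
    skipped = mat.index[~fit_mask]
    if len(skipped):
        logger.info("run_ewas: skipped %d CpG(s) below the complete-case floor", len(skipped))
    if not fit_mask.any():
        raise methio.EmptyResultError("no CpG passed the complete-case floor")

    Mf = M[fit_mask]
    obs = present[fit_mask].astype(float)
    Kf = Mf.shape[0]
    X = np.empty((Kf, n, q + 1))
    X[:, :, :q] = Xc[None, :, :]
    X[:, :, q] = np.where(np.isnan(Mf), 0.0, Mf)

    out = robust_scan(X, y, obs_weights=obs)
    effect = out["coef"][:, q]
    se = out["se"][:, q]
    p = out["p"][:, q]
    p = np.where(np.isnan(p), 1.0, p)
    records = pd.DataFrame(
        {
            "cpg_id": mat.index[fit_mask],
            "outcome": outcome,
            "cohort": cohort_id if cohort_id is not None else str(sub["cohort_id"].iloc[0]),
            "stratum": stratum,
            "n": out["n_obs"].astype(int),
            "effect": effect,
            "se": se,
            "p": p,
            "fdr": bh_fdr(p),
            "converged": out["converged"],
        }
    )
    n_unconv = int((~records["converged"]).sum())
    if n_unconv:
        logger.warning("run_ewas: %d CpG fit(s) flagged non-converged", n_unconv)
    records.attrs["n_skipped"] = int(len(skipped))
    records.attrs["skipped_cpgs"] = list(skipped)
    return records
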