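"""Polygenic-risk-score integration: adjusted scans, robustness, interactions.

Three operations quantify how much of a CpG-outcome association survives
conditioning on genetic risk:

* ``prs_adjusted_ewas`` — the standard scan with a standardised PRS appended
  to the covariates (samples without a PRS are dropped; the reduced n is
  carried on every record);
* ``robustness_compare`` — the "coefficient unchanged" screen: a CpG is
  robust when the relative coefficient change between the base and adjusted
  scans stays within ``rel_tol`` (default 10%, a declared package assumption:
  no numeric tolerance is standard in the field) *and* the adjusted scan keeps
  it at FDR < 0.05;
* ``interaction_scan`` — outcome ~ M + PRS + M x PRS + covariates, reporting
  the product-term coefficient per CpG.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import ewas, methio

logger = logging.getLogger(__name__)

ROBUSTNESS_COLUMNS = ["cpg_id", "outcome", "effect_base", "effect_adj", "rel_change", "is_robust"]


def _merge_prs(
    samples: pd.DataFrame, prs: pd.DataFrame, prs_column: str, min_n: int = 20
) -> pd.DataFrame:
    if prs_column not in prs.columns:
        raise methio.SchemaError(f"PRS table has no column '{prs_column}'")
    merged = samples.merge(prs[["sample_id", prs_column]], on="sample_id", how="inner")
    merged = merged[merged[prs_column].notna()]
    if len(merged) < min_n:
        raise ValueError(f"only {len(merged)} samples with a PRS; minimum is {min_n}")
    lost = len(samples) - len(merged)
    if lost:
        logger.info(
            "PRS merge dropped %d / %d samples (%.1f%%)", lost, len(samples), 100 * lost / len(samples)
        )
    sd = merged[prs_column].std()
    if sd == 0 or np.isnan(sd):
        raise ValueError(f"PRS column '{prs_column}' is constant; model not identifiable")
    merged[prs_column] = (merged[prs_column] - merged[prs_column].mean()) / sd
    return merged


def prs_adjusted_ewas(
    meth: pd.DataFrame,
    samples: pd.DataFrame,
    prs: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    prs_column: str = "prs_asthma",
    stratum: str = "all",
    cohort_id: str | None = None,
    min_n: int = 20,
) -> pd.DataFrame:
    """Re-run the EWAS with a standardised PRS as an additional covariate."""
    merged = _merge_prs(samples, prs, prs_column, min_n=min_n)
    return ewas.run_ewas(
        meth,
        merged,
        outcome,
        list(covariates) + [prs_column],
        stratum=stratum,
        cohort_id=cohort_id,
        min_n=min_n,
    )


def robustness_compare(
    base: pd.DataFrame,
    adjusted: pd.DataFrame,
    rel_tol: float = 0.10,
    abs_floor: float = 1e-6,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag CpGs whose coefficient "remained unchanged" after PRS adjustment.

    ``rel_change = |effect_adj - effect_base| / |effect_base|``; CpGs with
    ``|effect_base| < abs_floor`` instead compare the absolute change against
    ``rel_tol x`` the scan-median absolute base effect.  Robustness requires
    the change criterion *and* FDR < ``fdr_threshold`` in the adjusted scan.
    CpGs present in only one table are excluded with a log entry; the result
    is invariant to row order.
    """
    both = base.merge(adjusted, on="cpg_id", suffixes=("_base", "_adj"), how="inner")
    dropped = (set(base["cpg_id"]) | set(adjusted["cpg_id"])) - set(both["cpg_id"])
    if dropped:
        logger.info("robustness_compare: %d CpG(s) present in only one scan excluded", len(dropped))
    if len(both) and len({str(o) for o in both["outcome_base"]} | {str(o) for o in both["outcome_adj"]}) > 1:
        raise ValueError("base and adjusted scans analyse different outcomes")
    b = both["effect_base"].to_numpy(dtype=float)
    a = both["effect_adj"].to_numpy(dtype=float)
    med = np.median(np.abs(b)) if len(b) else 0.0
    tiny = np.abs(b) < abs_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(a - b) / np.abs(b)
    # degenerate base effects: judge the absolute change against the scan scale
    floor_scale = rel_tol * med if med > 0 else abs_floor
    rel = np.where(tiny, np.abs(a - b) / max(floor_scale / rel_tol, abs_floor), rel)
    change_ok = np.where(tiny, np.abs(a - b) <= floor_scale, rel <= rel_tol)
    fdr_ok = both["fdr_adj"].to_numpy(dtype=float) < fdr_threshold
    out = pd.DataFrame(
        {
            "cpg_id": both["cpg_id"],
            "outcome": both["outcome_base"],
            "effect_base": b,
            "effect_adj": a,
            "rel_change": rel,
            "is_robust": change_ok & fdr_ok,
        }
    ).sort_values("cpg_id", kind="stable").reset_index(drop=True)
    logger.info("robustness_compare: %d / %d CpG(s) robust", int(out["is_robust"].sum()), len(out))
    return out


def interaction_scan(
    meth: pd.DataFrame,
    samples: pd.DataFrame,
    prs: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    prs_column: str = "prs_asthma",
    stratum: str = "all",
    cohort_id: str | None = None,
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-CpG PRS x CpG interaction model (robust fit, sandwich SEs).

    Model: outcome ~ covariates + PRS + M + M x PRS; the reported effect is
    the product-term coefficient.  Constant PRS raises (no interaction
    identifiable).
    """
    merged = _merge_prs(samples, prs, prs_column, min_n=min_n)
    sub = merged if stratum == "all" else merged[merged["sex"] == stratum]
    if len(sub) == 0:
        raise ValueError(f"stratum '{stratum}' is empty")
    common = [s for s in meth.columns if s in set(sub["sample_id"])]
    sub = sub.set_index("sample_id").loc[common].reset_index()
    complete = sub[outcome].notna()
    for cov in covariates:
        complete &= sub[cov].notna()
    sub = sub[complete.to_numpy()]
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} complete-case samples; minimum is {min_n}")

    y = sub[outcome].to_numpy(dtype=float)
    Xc, _ = ewas.build_design(sub, list(covariates) + [prs_column])
    q = Xc.shape[1]
    prs_vec = sub[prs_column].to_numpy(dtype=float)

    mat = meth[sub["sample_id"]]
    M = mat.to_numpy(dtype=float)
    present = ~np.isnan(M)
    n_k = present.sum(axis=1)
    fit_mask = n_k >= (q + 1 + ewas.DF_GUARD)
    if not fit_mask.any():
        raise methio.EmptyResultError("no CpG passed the complete-case floor")
    Mf = np.where(np.isnan(M[fit_mask]), 0.0, M[fit_mask])
    obs = present[fit_mask].astype(float)
    K, n = Mf.shape
    X = np.empty((K, n, q + 2))
    X[:, :, :q] = Xc[None, :, :]
    X[:, :, q] = Mf
    X[:, :, q + 1] = Mf * prs_vec[None, :]
    out = ewas.robust_scan(X, y, obs_weights=obs)
    j = q + 1
    p = np.where(np.isnan(out["p"][:, j]), 1.0, out["p"][:, j])
    return pd.DataFrame(
        {
            "cpg_id": mat.index[fit_mask],
            "outcome": outcome,
            "cohort": cohort_id if cohort_id is not None else str(sub["cohort_id"].iloc[0]),
            "stratum": stratum,
            "n": out["n_obs"].astype(int),
            "effect": out["coef"][:, j],
            "se": out["se"][:, j],
            "p": p,
            "fdr": ewas.bh_fdr(p),
            "converged": out["converged"],
        }
    )
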