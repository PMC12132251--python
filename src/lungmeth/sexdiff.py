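"""Sex-stratified meta-analysis comparison: sex-specific and sex-divergent DMPs.

Two complementary views of the male/female stratified meta-analyses:

* **sex-specific sets** — set algebra on the retained (tiered) CpG sets of
  the two strata, with hyper-/hypo-methylation counts (sign of the pooled
  effect) per partition;
* **divergent DMPs** — CpGs whose pooled effects have opposite signs in the
  two sexes, reach FDR < threshold in at least one sex, and are directionally
  consistent (>= ``min_consistent_studies`` same-sign studies) within each sex
  separately.  CpGs with an exactly-zero pooled effect in either sex are
  excluded from divergence and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIVERGENT_COLUMNS = [
    "cpg_id", "outcome", "effect_f", "effect_m", "fdr_f", "fdr_m",
    "n_consistent_studies_f", "n_consistent_studies_m",
]


def _sign_counts(meta: pd.DataFrame) -> np.ndarray:
    """Per record: number of studies whose sign matches the pooled sign."""
    plus = meta["direction"].str.count(r"\+").to_numpy()
    minus = meta["direction"].str.count("-").to_numpy()
    pooled = np.sign(meta["effect"].to_numpy())
    return np.where(pooled > 0, plus, np.where(pooled < 0, minus, 0))


def sex_specific_sets(
    meta_f: pd.DataFrame,
    meta_m: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Partition two retained meta tables into female-only / male-only / shared.

    Expects tables from the same outcome and retention tier.  The returned
    dict also carries a ``summary`` frame with hyper (effect > 0) and hypo
    (effect < 0) counts per partition.
    """
    for a, b, col in ((meta_f, meta_m, "outcome"),):
        if len(a) and len(b) and str(a[col].iloc[0]) != str(b[col].iloc[0]):
            raise ValueError(f"{col} differs between the two tables")
    set_f = set(meta_f["cpg_id"])
    set_m = set(meta_m["cpg_id"])
    female_only = meta_f[~meta_f["cpg_id"].isin(set_m)].copy()
    male_only = meta_m[~meta_m["cpg_id"].isin(set_f)].copy()
    shared = meta_f[meta_f["cpg_id"].isin(set_m)].copy()
    rows = []
    for name, tab in (("female_only", female_only), ("male_only", male_only), ("shared", shared)):
        eff = tab["effect"].to_numpy() if len(tab) else np.array([])
        rows.append(
            {"set": name, "n": len(tab), "hyper": int((eff > 0).sum()), "hypo": int((eff < 0).sum())}
        )
    summary = pd.DataFrame(rows)
    logger.info(
        "sex_specific_sets: female_only=%d male_only=%d shared=%d",
        len(female_only), len(male_only), len(shared),
    )
    return {"female_only": female_only, "male_only": male_only, "shared": shared, "summary": summary}


def divergent_dmps(
    meta_f: pd.DataFrame,
    meta_m: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_consistent_studies: int = 2,
) -> pd.DataFrame:
    """Detect CpGs with opposite pooled effect direction between the sexes.

    Retention requires, per CpG present in both stratified meta tables:
    ``sign(effect_f) != sign(effect_m)`` with both nonzero, FDR < threshold
    in at least one sex, and at least ``min_consistent_studies`` studies whose
    sign matches the pooled sign within each sex.
    """
    merged = meta_f.merge(meta_m, on="cpg_id", suffixes=("_f", "_m"), how="inner")
    if len(merged) == 0:
        return pd.DataFrame(columns=DIVERGENT_COLUMNS)
    eff_f = merged["effect_f"].to_numpy()
    eff_m = merged["effect_m"].to_numpy()
    zero = (eff_f == 0) | (eff_m == 0)
    if zero.any():
        logger.info("divergent_dmps: %d CpG(s) with a zero pooled effect excluded", int(zero.sum()))
    opposite = (np.sign(eff_f) * np.sign(eff_m) < 0) & ~zero
    fdr_ok = (merged["fdr_f"].to_numpy() < fdr_threshold) | (
        merged["fdr_m"].to_numpy() < fdr_threshold
    )
    cons_f = _sign_counts(
        merged.rename(columns={"direction_f": "direction", "effect_f": "effect"})[
            ["direction", "effect"]
        ]
    )
    cons_m = _sign_counts(
        merged.rename(columns={"direction_m": "direction", "effect_m": "effect"})[
            ["direction", "effect"]
        ]
    )
    keep = opposite & fdr_ok & (cons_f >= min_consistent_studies) & (cons_m >= min_consistent_studies)
    out = pd.DataFrame(
        {
            "cpg_id": merged.loc[keep, "cpg_id"].to_numpy(),
            "outcome": merged.loc[keep, "outcome_f"].to_numpy(),
            "effect_f": eff_f[keep],
            "effect_m": eff_m[keep],
            "fdr_f": merged.loc[keep, "fdr_f"].to_numpy(),
            "fdr_m": merged.loc[keep, "fdr_m"].to_numpy(),
            "n_consistent_studies_f": cons_f[keep],
            "n_consistent_studies_m": cons_m[keep],
        }
    )
    # construction guarantees the sign constraint; assert on every output row
    assert (np.sign(out["effect_f"]) != np.sign(out["effect_m"])).all()
    logger.info("divergent_dmps: %d divergent CpG(s)", len(out))
    return out
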