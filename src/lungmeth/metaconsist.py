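"""Inverse-variance fixed-effects meta-analysis with direction-consistency tiers.

Per-cohort EWAS results are pooled METAL-style: a CpG enters the meta-analysis
when it reaches the discovery threshold (p < 0.05 by default) in at least one
cohort (or, in discovery-cohort mode, in a designated cohort), the pooled
effect is the inverse-variance weighted mean over every cohort in which the
CpG was measured, and a per-cohort direction string over the declared cohort
order summarises signs (``+``/``-``/``0``, ``?`` when absent).

Retention follows two tiers: ``all_studies`` (every cohort measured, all signs
agree, FDR < threshold) and ``two_of_three`` (at least two agreeing
non-missing signs, FDR < threshold) — the latter tier always contains the
former.  Cochran's Q is emitted informationally and never used for filtering.

Candidate regions use a simplified distance rule: per-chromosome position-sorted
hits are merged while consecutive gaps stay within ``max_gap_bp`` and runs of
at least ``min_cpgs`` sites are kept (a deliberate simplification of
kernel-based DMR callers).
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "cpg_id", "outcome", "stratum", "effect", "se", "z", "p", "fdr",
    "direction", "n_studies", "q_stat", "q_p",
]

TIERS = ("all_studies", "two_of_three")


def inverse_variance_meta(effects, ses) -> tuple[float, float, float, float]:
    """Fixed-effects pooling of one CpG: returns ``(effect, se, z, p)``.

    Missing (NaN) pairs are dropped; at least one non-missing pair is
    required and every supplied SE must be positive.
    """
    b = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    keep = ~(np.isnan(b) | np.isnan(s))
    b, s = b[keep], s[keep]
    if b.size == 0:
        raise ValueError("all studies missing; nothing to pool")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    effect = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = effect / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return effect, se, z, max(p, np.finfo(float).tiny)


def direction_symbols(effects: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Vectorised METAL-style symbols: '+', '-', '0' per study, '?' if absent.

    ``effects`` and ``present`` are (n_cpgs, n_studies) arrays.
    """
    sym = np.where(effects > 0, "+", np.where(effects < 0, "-", "0"))
    return np.where(present, sym, "?")


def join_directions(symbols: np.ndarray) -> np.ndarray:
    """Collapse an (n, k) symbol array into length-k direction strings."""
    out = symbols[:, 0].astype(object)
    for j in range(1, symbols.shape[1]):
        out = out + symbols[:, j].astype(object)
    return out.astype(str)


def run_meta(
    ewas_tables: dict[str, pd.DataFrame],
    discovery_p: float = 0.05,
    discovery_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Meta-analyse per-cohort EWAS tables (dict preserves cohort order).

    ``discovery_cohorts=None`` admits a CpG when its per-cohort p-value is
    below ``discovery_p`` in *any* cohort; passing cohort ids restricts the
    entry criterion to those cohorts (designated-discovery mode).  Pooling
    always uses every cohort in which the CpG was measured.
    """
    if not ewas_tables:
        raise ValueError("no EWAS tables supplied")
    cohorts = list(ewas_tables.keys())
    outcomes = {str(t["outcome"].iloc[0]) for t in ewas_tables.values() if len(t)}
    strata = {str(t["stratum"].iloc[0]) for t in ewas_tables.values() if len(t)}
    if len(outcomes) > 1 or len(strata) > 1:
        raise ValueError(f"tables mix outcomes {outcomes} or strata {strata}")
    outcome = outcomes.pop() if outcomes else ""
    stratum = strata.pop() if strata else "all"

    wide = None
    for cid in cohorts:
        t = ewas_tables[cid][["cpg_id", "effect", "se", "p"]].rename(
            columns={"effect": f"b_{cid}", "se": f"s_{cid}", "p": f"p_{cid}"}
        )
        wide = t if wide is None else wide.merge(t, on="cpg_id", how="outer")
    wide = wide.sort_values("cpg_id").reset_index(drop=True)

    B = wide[[f"b_{c}" for c in cohorts]].to_numpy(dtype=float)
    S = wide[[f"s_{c}" for c in cohorts]].to_numpy(dtype=float)
    P = wide[[f"p_{c}" for c in cohorts]].to_numpy(dtype=float)
    present = ~(np.isnan(B) | np.isnan(S))

    disc_cols = (
        np.ones(len(cohorts), dtype=bool)
        if discovery_cohorts is None
        else np.array([c in set(discovery_cohorts) for c in cohorts])
    )
    if discovery_cohorts is not None and not disc_cols.any():
        raise ValueError(f"discovery cohorts {discovery_cohorts} not among {cohorts}")
    entered = np.nansum(
        np.where(present[:, disc_cols], P[:, disc_cols] < discovery_p, False), axis=1
    ) > 0
    if not entered.any():
        logger.warning("run_meta: no CpG passed the discovery threshold p<%g", discovery_p)
        return pd.DataFrame(columns=META_COLUMNS)

    B, S, P, present = B[entered], S[entered], P[entered], present[entered]
    W = np.where(present, 1.0 / S**2, 0.0)
    sw = W.sum(axis=1)
    eff = np.where(present, W * B, 0.0).sum(axis=1) / sw
    se = 1.0 / np.sqrt(sw)
    z = eff / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    n_studies = present.sum(axis=1)
    # Cochran's Q (informational): sum of w_k (b_k - pooled)^2
    q_stat = np.where(present, W * (B - eff[:, None]) ** 2, 0.0).sum(axis=1)
    q_df = np.maximum(n_studies - 1, 0)
    q_p = np.where(q_df > 0, stats.chi2.sf(q_stat, np.maximum(q_df, 1)), np.nan)

    directions = join_directions(direction_symbols(B, present))
    meta = pd.DataFrame(
        {
            "cpg_id": wide.loc[entered, "cpg_id"].to_numpy(),
            "outcome": outcome,
            "stratum": stratum,
            "effect": eff,
            "se": se,
            "z": z,
            "p": pval,
            "fdr": bh_fdr(pval),
            "direction": directions,
            "n_studies": n_studies,
            "q_stat": q_stat,
            "q_p": q_p,
        }
    )
    zero_dirs = meta["direction"].str.contains("0", regex=False)
    if zero_dirs.any():
        logger.info("run_meta: %d CpG(s) with an exactly-zero study effect", int(zero_dirs.sum()))
    return meta


# ---------------------------------------------------------------------------
# consistency tiers
# ---------------------------------------------------------------------------

def _direction_counts(directions: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    plus = directions.str.count(r"\+").to_numpy()
    minus = directions.str.count("-").to_numpy()
    missing = directions.str.count(r"\?").to_numpy()
    return plus, minus, missing


def consistent_mask(directions: pd.Series, tier: str) -> np.ndarray:
    """Boolean retention mask for a direction-string series under a tier.

    ``all_studies``: every cohort measured and every sign agrees (a ``0``
    symbol counts as disagreement).  ``two_of_three``: at least two agreeing
    non-missing signs (a disagreeing or missing remainder is tolerated).
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    plus, minus, missing = _direction_counts(directions)
    length = directions.str.len().to_numpy()
    if tier == "all_studies":
        return ((plus == length) | (minus == length)) & (missing == 0)
    return np.maximum(plus, minus) >= 2


def consistency_filter(
    meta: pd.DataFrame,
    tier: str = "all_studies",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Retain meta records satisfying the tier's direction rule at FDR < threshold."""
    if "fdr" not in meta.columns:
        raise ValueError("meta table has no fdr column")
    if len(meta) == 0:
        out = meta.copy()
        out["tier"] = pd.Series(dtype=str)
        return out
    keep = consistent_mask(meta["direction"], tier) & (meta["fdr"] < fdr_threshold).to_numpy()
    out = meta[keep].copy()
    out["tier"] = tier
    logger.info("consistency_filter[%s]: retained %d / %d", tier, len(out), len(meta))
    return out


# ---------------------------------------------------------------------------
# multi-trait overlap
# ---------------------------------------------------------------------------

def multi_trait_overlap(retained_sets: dict[str, pd.DataFrame | set]) -> dict[str, pd.DataFrame]:
    """Upset-style intersection counting of retained CpG sets across outcomes.

    Accepts per-outcome retained meta tables (``cpg_id`` column) or plain
    sets.  Returns ``per_cpg`` (cpg_id, n_traits, pattern), ``intersections``
    (exclusive per-pattern counts) and ``at_least`` (CpGs retained for >= k
    outcomes, k = 1..n_outcomes).
    """
    if len(retained_sets) < 2:
        raise ValueError("need at least two outcome sets")
    outcomes = list(retained_sets.keys())
    sets = {
        o: set(v["cpg_id"]) if isinstance(v, pd.DataFrame) else set(v)
        for o, v in retained_sets.items()
    }
    universe = sorted(set().union(*sets.values()))
    member = np.array([[c in sets[o] for o in outcomes] for c in universe], dtype=bool)
    n_traits = member.sum(axis=1)
    patterns = ["&".join(o for o, m in zip(outcomes, row) if m) for row in member]
    per_cpg = pd.DataFrame({"cpg_id": universe, "n_traits": n_traits, "pattern": patterns})
    intersections = (
        per_cpg.groupby("pattern").size().rename("count").reset_index().sort_values(
            "count", ascending=False, kind="stable"
        ).reset_index(drop=True)
    )
    ks = np.arange(1, len(outcomes) + 1)
    at_least = pd.DataFrame({"k": ks, "count": [(n_traits >= k).sum() for k in ks]})
    return {"per_cpg": per_cpg, "intersections": intersections, "at_least": at_least}


# ---------------------------------------------------------------------------
# region rule
# ---------------------------------------------------------------------------

def region_filter(
    hits,
    annotation: pd.DataFrame,
    max_gap_bp: int = 1000,
    min_cpgs: int = 4,
) -> pd.DataFrame:
    """Distance-merge retained CpGs into candidate regions (>= min_cpgs kept).

    ``hits`` may be a retained meta table (``cpg_id`` column) or an iterable
    of CpG ids.  CpGs absent from the annotation raise an error listing them.
    """
    ids = list(hits["cpg_id"]) if isinstance(hits, pd.DataFrame) else list(hits)
    ann = annotation.set_index("cpg_id")
    missing = [c for c in ids if c not in ann.index]
    if missing:
        raise ValueError(f"hit CpG(s) missing from annotation: {missing[:10]}")
    if not ids:
        return pd.DataFrame(columns=["region_id", "chrom", "start", "end", "n_cpgs", "cpg_ids"])
    tab = ann.loc[ids, ["chrom", "pos"]].reset_index().sort_values(
        ["chrom", "pos"], kind="stable"
    )
    regions = []
    for chrom, grp in tab.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        cpgs = grp["cpg_id"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_bp)[0] + 1
        for run_idx in np.split(np.arange(len(pos)), breaks):
            if len(run_idx) >= min_cpgs:
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[run_idx[0]]),
                        "end": int(pos[run_idx[-1]]),
                        "n_cpgs": int(len(run_idx)),
                        "cpg_ids": ",".join(cpgs[run_idx]),
                    }
                )
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_cpgs", "cpg_ids"])
    out.insert(0, "region_id", [f"region{i + 1:04d}" for i in range(len(out))])
    logger.info("region_filter: %d region(s) with >= %d CpGs", len(out), min_cpgs)
    return out


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """0-based half-open BED export of candidate regions."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int) - 1,
            "end": regions["end"].astype(int),
            "name": regions["region_id"],
            "score": regions["n_cpgs"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
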