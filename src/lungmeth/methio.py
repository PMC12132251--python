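"""Data model, file I/O and scale transforms for methylation matrices.

Conventions used throughout the package:

* A **beta matrix** is a :class:`pandas.DataFrame` with CpG identifiers on the
  index (name ``cpg_id``) and sample identifiers on the columns.  Non-missing
  entries lie strictly inside the open interval (0, 1).
* An **M-value matrix** shares the axes and holds ``log2(beta / (1 - beta))``,
  the variance-stabilised scale on which all regressions run.
* A **sample table** is a DataFrame with one row per sample carrying at least
  ``sample_id``, ``cohort_id`` and ``sex`` (coded ``F``/``M``), plus covariates
  and the spirometry outcomes.
* A **CpG annotation** table has one row per CpG with 1-based positions
  (``cpg_id, chrom, pos, gene, island_relation, gene_context``); the BED export
  is 0-based half-open.

All tabular I/O is plain TSV (gzip transparent via the ``.gz`` suffix), so any
intermediate of the pipeline can be inspected with standard shell tools.
"""

from __future__ import annotations

import logging
import numbers
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: clamping bound applied to beta values that sit exactly on 0 or 1
BETA_EPS = 1e-6

OUTCOME_COLUMNS = ("FEV1", "FVC", "FEV1_FVC", "FEF2575", "FEF2575_FVC")

ANNOTATION_COLUMNS = ("cpg_id", "chrom", "pos", "gene", "island_relation", "gene_context")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


class DomainError(ValueError):
    """A value fell outside its mathematically valid domain."""


class EmptyResultError(ValueError):
    """An operation removed every record and has nothing left to return."""


class SchemaError(ValueError):
    """A table is missing required columns or violates its invariants."""


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------

def _describe_offenders(beta: pd.DataFrame, bad: np.ndarray, limit: int = 5) -> str:
    rows, cols = np.nonzero(bad)
    items = [
        f"{beta.index[r]}/{beta.columns[c]}" for r, c in zip(rows[:limit], cols[:limit])
    ]
    more = "" if len(rows) <= limit else f" (+{len(rows) - limit} more)"
    return ", ".join(items) + more


def clamp_beta(beta, eps: float = BETA_EPS):
    """Clamp beta values into ``[eps, 1 - eps]``, warning if anything moved."""
    arr = beta.to_numpy(dtype=float) if isinstance(beta, pd.DataFrame) else np.asarray(beta, dtype=float)
    moved = np.nansum((arr <= 0) | (arr >= 1))
    if moved:
        logger.warning("clamped %d beta value(s) at the [%g, %g] boundary", moved, eps, 1 - eps)
    clipped = np.clip(arr, eps, 1.0 - eps)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(clipped, index=beta.index, columns=beta.columns)
    if isinstance(beta, numbers.Number):
        return float(clipped)
    return clipped


def beta_to_m(beta, *, strict: bool = False):
    """Logit2 transform ``M = log2(beta / (1 - beta))``.

    Missing values propagate.  Values at or outside the (0, 1) boundary are
    clamped to ``[BETA_EPS, 1 - BETA_EPS]`` with a logged warning; under
    ``strict=True`` they raise :class:`DomainError` naming the offending
    CpG/sample when the input is a DataFrame.
    """
    is_frame = isinstance(beta, pd.DataFrame)
    is_series = isinstance(beta, pd.Series)
    is_scalar = isinstance(beta, numbers.Number)
    arr = beta.to_numpy(dtype=float) if (is_frame or is_series) else np.asarray(beta, dtype=float)
    bad = ~np.isnan(arr) & ((arr <= 0.0) | (arr >= 1.0))
    if bad.any():
        if strict:
            if is_frame:
                raise DomainError(
                    "beta values outside (0,1) at: " + _describe_offenders(beta, bad)
                )
            raise DomainError(f"{int(bad.sum())} beta value(s) outside the open interval (0,1)")
        arr = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
        logger.warning("beta_to_m clamped %d boundary value(s)", int(bad.sum()))
    m = np.log2(arr / (1.0 - arr))
    if is_frame:
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if is_series:
        return pd.Series(m, index=beta.index, name=beta.name)
    if is_scalar:
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**m / (1 + 2**m)``, mapped into (0, 1)."""
    is_frame = isinstance(m, pd.DataFrame)
    is_series = isinstance(m, pd.Series)
    is_scalar = isinstance(m, numbers.Number)
    arr = m.to_numpy(dtype=float) if (is_frame or is_series) else np.asarray(m, dtype=float)
    # expit formulation is overflow-safe for large |m|
    from scipy.special import expit

    beta = expit(arr * np.log(2.0))
    if is_frame:
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if is_series:
        return pd.Series(beta, index=m.index, name=m.name)
    if is_scalar:
        return float(beta)
    return beta


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_beta_matrix(beta: pd.DataFrame) -> None:
    """Check axis uniqueness and the open-interval range; raise on violation."""
    if beta.index.has_duplicates:
        dupes = beta.index[beta.index.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicate cpg_id in beta matrix: {dupes}")
    if beta.columns.has_duplicates:
        dupes = beta.columns[beta.columns.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicate sample_id in beta matrix: {dupes}")
    arr = beta.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & ((arr <= 0.0) | (arr >= 1.0))
    if bad.any():
        raise DomainError("beta values outside (0,1) at: " + _describe_offenders(beta, bad))


def validate_sample_table(samples: pd.DataFrame, require_outcomes: bool = True) -> None:
    required = ["sample_id", "cohort_id", "sex"]
    if require_outcomes:
        required += list(OUTCOME_COLUMNS)
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table missing column(s): {missing}")
    if samples["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample table")
    bad_sex = ~samples["sex"].isin(["F", "M"]) & samples["sex"].notna()
    if bad_sex.any():
        raise SchemaError(f"sex must be F or M; offending rows: {samples.loc[bad_sex, 'sample_id'].tolist()[:5]}")
    cell_cols = [c for c in samples.columns if c.startswith("cell_")]
    if cell_cols:
        props = samples[cell_cols].to_numpy(dtype=float)
        if np.nanmin(props) < -1e-9:
            raise SchemaError("negative cell-type proportion")
        if np.nanmax(props.sum(axis=1)) > 1.0 + 1e-6:
            raise SchemaError("cell-type proportions sum above 1")


def validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ("cpg_id", "chrom", "pos") if c not in annotation.columns]
    if missing:
        raise SchemaError(f"annotation missing column(s): {missing}")
    if annotation["cpg_id"].duplicated().any():
        raise SchemaError("duplicate cpg_id in annotation")
    if (annotation["pos"] < 1).any():
        raise SchemaError("annotation positions must be 1-based (pos >= 1)")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    beta: pd.DataFrame,
    max_missing_frac: float = 0.1,
    min_sd: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop CpGs that are too missing or (nearly) invariant.

    Returns ``(filtered, report)`` where *report* lists one row per dropped
    CpG with columns ``cpg_id`` and ``reason`` (``missingness`` before
    ``low_variance`` when both apply).  Retained CpG order is preserved and
    the operation is idempotent.  Raises :class:`EmptyResultError` when no
    CpG survives.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in [0, 1]")
    if min_sd < 0:
        raise ValueError("min_sd must be non-negative")
    arr = beta.to_numpy(dtype=float)
    miss_frac = np.isnan(arr).mean(axis=1)
    sd = np.nanstd(arr, axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(arr.shape[0])
    sd = np.nan_to_num(sd, nan=0.0)
    too_missing = miss_frac > max_missing_frac
    too_flat = sd < min_sd
    reasons = []
    for cpg, m_flag, v_flag in zip(beta.index, too_missing, too_flat):
        if m_flag:
            reasons.append((cpg, "missingness"))
        elif v_flag:
            reasons.append((cpg, "low_variance"))
    report = pd.DataFrame(reasons, columns=["cpg_id", "reason"])
    keep = ~(too_missing | too_flat)
    if not keep.any():
        raise EmptyResultError("qc_filter removed every CpG")
    filtered = beta.loc[keep]
    logger.info("qc_filter: kept %d / %d CpGs (%d dropped)", keep.sum(), len(keep), len(report))
    return filtered, report


# ---------------------------------------------------------------------------
# readers / writers (all TSV; gzip via suffix)
# ---------------------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a CpG x sample matrix as TSV (index column named cpg_id)."""
    matrix.rename_axis("cpg_id").to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cpg_id")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_table(path, require_outcomes: bool = True) -> pd.DataFrame:
    samples = read_table(path)
    validate_sample_table(samples, require_outcomes=require_outcomes)
    return samples


def read_annotation(path) -> pd.DataFrame:
    annotation = read_table(path)
    validate_annotation(annotation)
    return annotation


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED export of the annotation: 0-based half-open single-base intervals."""
    validate_annotation(annotation)
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["pos"].astype(int) - 1,
            "end": annotation["pos"].astype(int),
            "name": annotation["cpg_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def is_sex_chromosome(chrom: Iterable[str]) -> np.ndarray:
    """Boolean mask for chrX/chrY style chromosome labels."""
    return np.asarray([str(c) in SEX_CHROMOSOMES for c in chrom])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
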