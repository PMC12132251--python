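"""Synthetic cohort generator with planted methylation-outcome truth.

The generator emulates the design of a three-cohort childhood lung-function
methylation study: two childhood asthma cohorts and one birth cohort profiled
in cord blood, with sample sizes defaulting to 788 / 703 / 572.  For each
cohort it draws a genome-like beta-value matrix (bimodal per-CpG means around
0.1 and 0.9 with a minority of intermediate CpGs), a sample table with sex,
age (gestational age for the birth cohort), height, smoke exposure and
Dirichlet cell-type proportions, and five spirometry outcomes built as linear
functions of the causal CpGs' M-values plus covariates plus Gaussian noise.

Every planted effect is recorded in a truth table so downstream stages
(EWAS, meta-analysis, sex-divergence detection, network estimation) can be
scored against known ground truth.  All generators are pure functions of
their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import methio

OUTCOMES = methio.OUTCOME_COLUMNS

#: baseline level and residual-noise multiplier per outcome (spirometry units:
#: L, L, %, L/s, ratio)
OUTCOME_BASELINES = {
    "FEV1": 2.2,
    "FVC": 2.8,
    "FEV1_FVC": 82.0,
    "FEF2575": 2.0,
    "FEF2575_FVC": 0.85,
}
OUTCOME_NOISE_SCALE = {
    "FEV1": 1.0,
    "FVC": 1.2,
    "FEV1_FVC": 8.0,
    "FEF2575": 1.0,
    "FEF2575_FVC": 0.25,
}

#: fixed covariate coefficients on the FEV1 scale; other outcomes reuse them
#: multiplied by their noise scale so signal-to-noise is comparable
COVARIATE_EFFECTS = {
    "age": 0.06,          # L per year
    "height": 0.015,      # L per cm
    "sex_male": 0.12,     # L
    "smoke_exposure": -0.08,
    "cell_Gran": -0.30,
}

CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")
CELL_DIRICHLET_ALPHA = (6.0, 3.0, 1.5, 2.0, 2.0, 16.0)


class ConfigError(ValueError):
    """A generator configuration field is invalid (message names the field)."""


@dataclass(frozen=True)
class CohortConfig:
    """Configuration for one synthetic cohort.

    ``effect_mean``/``effect_sd`` parameterise the Gaussian from which causal
    effect sizes (outcome units per M-value unit) are drawn; ``noise_sd`` is
    the residual SD of the target outcomes on the FEV1 (litre) scale.
    ``baseline_beta_shape`` is ``(concentration, bimodal_fraction)`` of the
    per-CpG beta-value distribution.  ``effect_attenuation`` scales every
    planted effect (0.5 for the birth cohort by default study configuration,
    emulating weaker cord-blood signal).
    """

    cohort_id: str
    n_samples: int
    n_cpgs: int
    frac_causal: float = 0.05
    effect_mean: float = 0.5
    effect_sd: float = 0.1
    noise_sd: float = 1.0
    frac_sex_divergent: float = 0.0
    baseline_beta_shape: tuple[float, float] = (50.0, 0.8)
    seed: int = 0
    birth_cohort: bool = False
    effect_attenuation: float = 1.0
    target_outcomes: tuple[str, ...] = ("FEV1",)
    frac_female: float = 0.42
    frac_chr_x: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ConfigError(f"n_samples must be >= 20, got {self.n_samples}")
        if self.n_cpgs < 10:
            raise ConfigError(f"n_cpgs must be >= 10, got {self.n_cpgs}")
        for name in ("frac_causal", "frac_sex_divergent", "frac_female", "frac_chr_x"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.effect_attenuation < 0:
            raise ConfigError(f"effect_attenuation must be >= 0, got {self.effect_attenuation}")
        unknown = [o for o in self.target_outcomes if o not in OUTCOMES]
        if unknown:
            raise ConfigError(f"target_outcomes contains unknown outcome(s) {unknown}")
        conc, bifrac = self.baseline_beta_shape
        if conc <= 0 or not (0.0 <= bifrac <= 1.0):
            raise ConfigError(f"baseline_beta_shape invalid: {self.baseline_beta_shape}")


_STRUCTURES = ("chain", "star", "random-sparse")


@dataclass(frozen=True)
class PrecisionSpec:
    """Structure of a planted precision matrix for one sex stratum."""

    n_nodes: int
    structure: str = "chain"
    edge_strength: float = 0.3
    stratum: str = "female"

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ConfigError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if self.structure not in _STRUCTURES:
            raise ConfigError(f"structure must be one of {_STRUCTURES}, got {self.structure!r}")
        if not (0.0 < abs(self.edge_strength) < 1.0):
            raise ConfigError(f"edge_strength must have magnitude in (0,1), got {self.edge_strength}")


def default_study_configs(
    n_cpgs: int = 2000,
    frac_causal: float = 0.05,
    frac_sex_divergent: float = 0.0,
    seed: int = 0,
    noise_sd: float = 1.0,
    target_outcomes: tuple[str, ...] = ("FEV1",),
) -> list[CohortConfig]:
    """The default three-cohort study condition (two childhood + one birth).

    Sample sizes 788 / 703 / 572 mirror a childhood replication cohort, a
    childhood discovery cohort and a cord-blood birth cohort; the birth cohort
    carries gestational age instead of age and half-attenuated effects.
    """
    common = dict(
        n_cpgs=n_cpgs,
        frac_causal=frac_causal,
        frac_sex_divergent=frac_sex_divergent,
        noise_sd=noise_sd,
        target_outcomes=target_outcomes,
    )
    return [
        CohortConfig(cohort_id="CHILD_A", n_samples=788, seed=seed * 1000 + 1, **common),
        CohortConfig(cohort_id="CHILD_B", n_samples=703, seed=seed * 1000 + 2, **common),
        CohortConfig(
            cohort_id="BIRTH",
            n_samples=572,
            seed=seed * 1000 + 3,
            birth_cohort=True,
            effect_attenuation=0.5,
            **common,
        ),
    ]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

#: CpGs fall in clusters of this many consecutive ids (a 2-20 kb gap opens
#: each cluster; within-cluster spacing is 50-300 bp)
CLUSTER_PERIOD = 8


def _chrom_assignment(n_cpgs: int, frac_chr_x: float = 0.0) -> list[str]:
    """Contiguous index blocks per chromosome (consecutive ids are neighbours)."""
    n_x = int(round(frac_chr_x * n_cpgs))
    n_auto = n_cpgs - n_x
    per_chrom = int(np.ceil(n_auto / 22))
    chroms = [f"chr{i // per_chrom + 1}" for i in range(n_auto)]
    return chroms + ["chrX"] * n_x


def generate_annotation(n_cpgs: int, seed: int = 0, frac_chr_x: float = 0.0) -> pd.DataFrame:
    """Deterministic CpG annotation shared by all cohorts of one study.

    Consecutive CpG ids occupy contiguous blocks of chr1..chr22 (optionally a
    trailing chrX block) with island-like spacing: ~70% of inter-CpG gaps are
    50-300 bp (clustered sites) and the rest 2-20 kb (isolated sites), so
    distance-based region merging sees realistic runs and singletons.
    """
    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    chroms = _chrom_assignment(n_cpgs, frac_chr_x)
    # every CLUSTER_PERIOD-th CpG opens a new cluster (loose gap); within a
    # cluster neighbours sit 50-300 bp apart
    tight = (np.arange(n_cpgs) % CLUSTER_PERIOD) != 0
    gaps = np.where(
        tight, rng.integers(50, 300, size=n_cpgs), rng.integers(2000, 20_000, size=n_cpgs)
    )
    ann = pd.DataFrame({"cpg_id": cpg_ids, "chrom": chroms, "gap": gaps})
    ann["pos"] = ann.groupby("chrom")["gap"].cumsum() + 10_000
    ann = ann.drop(columns="gap")
    islands = rng.choice(
        ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"],
        p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4],
        size=n_cpgs,
    )
    contexts = rng.choice(
        ["TSS1500", "TSS200", "5'UTR", "Body", "3'UTR", "ExonBnd", ""],
        p=[0.1, 0.05, 0.1, 0.45, 0.05, 0.05, 0.2],
        size=n_cpgs,
    )
    genes = np.where(
        rng.uniform(size=n_cpgs) < 0.7,
        [f"GENE{i // 8:05d}" for i in range(n_cpgs)],
        "",
    )
    ann["gene"] = genes
    ann["island_relation"] = islands
    ann["gene_context"] = contexts
    return ann[list(methio.ANNOTATION_COLUMNS)]


# ---------------------------------------------------------------------------
# single cohort
# ---------------------------------------------------------------------------

def _draw_beta_matrix(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    conc, bifrac = config.baseline_beta_shape
    n_cpgs, n_samples = config.n_cpgs, config.n_samples
    kind = rng.uniform(size=n_cpgs)
    mu = np.where(
        kind < bifrac / 2,
        rng.uniform(0.05, 0.15, size=n_cpgs),
        np.where(
            kind < bifrac,
            rng.uniform(0.85, 0.95, size=n_cpgs),
            rng.uniform(0.30, 0.70, size=n_cpgs),
        ),
    )
    a = mu * conc
    b = (1.0 - mu) * conc
    beta = rng.beta(a[:, None], b[:, None], size=(n_cpgs, n_samples))
    beta = np.clip(beta, methio.BETA_EPS, 1.0 - methio.BETA_EPS)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    sample_ids = [f"{config.cohort_id}_s{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(beta, index=pd.Index(cpg_ids, name="cpg_id"), columns=sample_ids)


def _draw_sample_covariates(rng: np.random.Generator, config: CohortConfig, sample_ids) -> pd.DataFrame:
    n = config.n_samples
    sex = np.where(rng.uniform(size=n) < config.frac_female, "F", "M")
    if config.birth_cohort:
        gest = rng.normal(39.2, 1.5, size=n).clip(30, 43)
        age = np.zeros(n)
        height = 50.0 + 0.9 * (gest - 39.0) + rng.normal(0, 2.0, size=n)
        smoke = (rng.uniform(size=n) < 0.05).astype(int)
    else:
        gest = np.full(n, np.nan)
        age = rng.normal(10.5, 2.0, size=n).clip(5, 18)
        height = 85.0 + 4.7 * age + rng.normal(0, 6.0, size=n)
        smoke = (rng.uniform(size=n) < 0.3).astype(int)
    cells = rng.dirichlet(CELL_DIRICHLET_ALPHA, size=n)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort_id": config.cohort_id,
            "sex": sex,
            "age": age,
            "gestational_age": gest,
            "height": height,
            "smoke_exposure": smoke,
        }
    )
    for j, ct in enumerate(CELL_TYPES):
        samples[f"cell_{ct}"] = cells[:, j]
    return samples


def _draw_planted_effects(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    """Per-CpG planted truth (single-cohort path): effect_all/effect_f/effect_m."""
    n_causal = int(round(config.frac_causal * config.n_cpgs))
    idx = np.sort(rng.choice(config.n_cpgs, size=n_causal, replace=False))
    effects = rng.normal(config.effect_mean, config.effect_sd, size=n_causal)
    effects *= config.effect_attenuation
    n_div = int(round(config.frac_sex_divergent * n_causal))
    div_pick = rng.choice(n_causal, size=n_div, replace=False) if n_div else np.array([], dtype=int)
    return _effects_frame(config.n_cpgs, idx, effects, div_pick)


def _effects_frame(n_cpgs: int, causal_idx: np.ndarray, effects: np.ndarray, div_pos: np.ndarray) -> pd.DataFrame:
    """Assemble the dense per-CpG effect table from causal indices."""
    eff_all = np.zeros(n_cpgs)
    eff_f = np.zeros(n_cpgs)
    eff_m = np.zeros(n_cpgs)
    is_causal = np.zeros(n_cpgs, dtype=bool)
    is_div = np.zeros(n_cpgs, dtype=bool)
    is_causal[causal_idx] = True
    eff_f[causal_idx] = effects
    eff_m[causal_idx] = effects
    eff_all[causal_idx] = effects
    div_idx = causal_idx[div_pos]
    # exact sign flip: female keeps +e, male gets -e; pooled effect is 0
    eff_m[div_idx] = -eff_f[div_idx]
    eff_all[div_idx] = 0.0
    is_div[div_idx] = True
    return pd.DataFrame(
        {
            "cpg_index": np.arange(n_cpgs),
            "effect_all": eff_all,
            "effect_female": eff_f,
            "effect_male": eff_m,
            "is_causal": is_causal,
            "is_divergent": is_div,
        }
    )


def _build_outcomes(
    rng: np.random.Generator,
    config: CohortConfig,
    m_values: np.ndarray,
    samples: pd.DataFrame,
    planted: pd.DataFrame,
) -> pd.DataFrame:
    """Outcome = baseline + sum_c effect_c(sex) * centred M_c + covariates + noise."""
    n = config.n_samples
    sex_male = (samples["sex"] == "M").to_numpy()
    causal = planted[planted["is_causal"]]
    contrib = np.zeros(n)
    if len(causal):
        idx = causal["cpg_index"].to_numpy()
        Mc = m_values[idx]  # (n_causal, n)
        Mc = Mc - Mc.mean(axis=1, keepdims=True)
        eff = np.where(
            sex_male[None, :],
            causal["effect_male"].to_numpy()[:, None],
            causal["effect_female"].to_numpy()[:, None],
        )
        contrib = (eff * Mc).sum(axis=0)
    age_like = samples["gestational_age"].to_numpy() if config.birth_cohort else samples["age"].to_numpy()
    cov_signal = (
        COVARIATE_EFFECTS["age"] * (age_like - np.nanmean(age_like))
        + COVARIATE_EFFECTS["height"] * (samples["height"].to_numpy() - samples["height"].mean())
        + COVARIATE_EFFECTS["sex_male"] * sex_male
        + COVARIATE_EFFECTS["smoke_exposure"] * samples["smoke_exposure"].to_numpy()
        + COVARIATE_EFFECTS["cell_Gran"] * (samples["cell_Gran"].to_numpy() - samples["cell_Gran"].mean())
    )
    out = {}
    for outcome in OUTCOMES:
        scale = OUTCOME_NOISE_SCALE[outcome]
        y = OUTCOME_BASELINES[outcome] + scale * cov_signal
        if outcome in config.target_outcomes:
            y = y + scale * contrib
        y = y + rng.normal(0.0, config.noise_sd * scale, size=n)
        out[outcome] = y
    return pd.DataFrame(out)


def _truth_table(config: CohortConfig, planted: pd.DataFrame) -> pd.DataFrame:
    """One row per CpG x target outcome; effects on the outcome's own scale."""
    cpg_ids = [f"cg{i:08d}" for i in range(config.n_cpgs)]
    frames = []
    for outcome in config.target_outcomes:
        scale = OUTCOME_NOISE_SCALE[outcome]
        frames.append(
            pd.DataFrame(
                {
                    "cpg_id": cpg_ids,
                    "outcome": outcome,
                    "effect_all": planted["effect_all"].to_numpy() * scale,
                    "effect_female": planted["effect_female"].to_numpy() * scale,
                    "effect_male": planted["effect_male"].to_numpy() * scale,
                    "is_causal": planted["is_causal"].to_numpy(),
                    "is_divergent": planted["is_divergent"].to_numpy(),
                    "hub_label": "none",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(
    config: CohortConfig,
    planted: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: ``(beta_matrix, sample_table, truth_table)``.

    ``planted`` optionally supplies a pre-built per-CpG effect table (as used
    by :func:`generate_multi_cohort` to share truth across cohorts); when
    omitted, effects are drawn from the config's own effect distribution.
    Identical config (and planted table) reproduces bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    beta = _draw_beta_matrix(rng, config)
    samples = _draw_sample_covariates(rng, config, list(beta.columns))
    if planted is None:
        planted = _draw_planted_effects(rng, config)
    m_values = methio.beta_to_m(beta).to_numpy()
    outcomes = _build_outcomes(rng, config, m_values, samples, planted)
    samples = pd.concat([samples, outcomes], axis=1)
    truth = _truth_table(config, planted)
    methio.validate_beta_matrix(beta)
    return beta, samples, truth


# ---------------------------------------------------------------------------
# multi-cohort with shared truth
# ---------------------------------------------------------------------------

#: fraction of the shared causal budget planted as contiguous index runs of
#: 4-6 CpGs (region-like truth for the distance-merge rule); the remainder is
#: scattered singletons
REGION_CAUSAL_FRAC = 0.3
REGION_RUN_LENGTHS = (4, 6)


def _choose_causal(
    rng: np.random.Generator,
    n_cpgs: int,
    n_causal: int,
    region_frac: float = REGION_CAUSAL_FRAC,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick causal CpG indices: part contiguous runs, part scattered.

    Returns ``(indices, group)`` where ``group`` labels each index with its
    run (scattered CpGs get singleton groups).  Runs never cross the
    chromosome blocks laid down by :func:`generate_annotation`.
    """
    lo, hi = REGION_RUN_LENGTHS
    per_chrom = int(np.ceil(n_cpgs / 22))
    budget = int(round(region_frac * n_causal))
    if n_causal >= lo + 2:
        # always plant at least one full run so the region rule has a truth
        # (while leaving at least two scattered causal CpGs)
        budget = max(budget, lo)
    taken: set[int] = set()
    runs: list[np.ndarray] = []
    attempts = 0
    while budget >= lo and attempts < 200:
        attempts += 1
        length = int(rng.integers(lo, min(hi, budget) + 1))
        start = int(rng.integers(0, n_cpgs - length + 1))
        idx = np.arange(start, start + length)
        if start // per_chrom != (start + length - 1) // per_chrom:
            continue  # would straddle a chromosome boundary
        if any(j % CLUSTER_PERIOD == 0 for j in idx[1:]):
            continue  # would straddle a cluster boundary (loose gap)
        if taken.intersection(idx):
            continue
        runs.append(idx)
        taken.update(idx.tolist())
        budget -= length
    n_scatter = n_causal - sum(len(r) for r in runs)
    free = np.setdiff1d(np.arange(n_cpgs), np.fromiter(taken, dtype=int, count=len(taken)))
    scatter = rng.choice(free, size=n_scatter, replace=False)
    indices = np.concatenate(runs + [scatter]) if runs else scatter
    group = np.concatenate(
        [np.full(len(r), g) for g, r in enumerate(runs)]
        + [np.arange(len(runs), len(runs) + n_scatter)]
    ) if len(indices) else np.array([], dtype=int)
    order = np.argsort(indices)
    return indices[order].astype(int), group[order].astype(int)

def generate_multi_cohort(
    configs: list[CohortConfig],
    shared_truth_frac: float = 1.0,
) -> list[tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]]:
    """Generate several cohorts whose causal CpGs partially overlap.

    A ``shared_truth_frac`` fraction of each cohort's causal CpGs is common to
    every cohort with a common effect **sign** (magnitudes redrawn per cohort
    from that cohort's effect distribution); the remaining causal CpGs are
    cohort-private and disjoint across cohorts.  Sex-divergent CpGs are
    assigned within the shared set, with the same female-positive/male-negative
    flip in every cohort, so cross-study divergence detection has a truth.
    """
    if len(configs) < 2:
        raise ConfigError("need >= 2 cohort configs")
    if not (0.0 <= shared_truth_frac <= 1.0):
        raise ConfigError(f"shared_truth_frac must be in [0, 1], got {shared_truth_frac}")
    n_cpgs = configs[0].n_cpgs
    for c in configs:
        c.validate()
        if c.n_cpgs != n_cpgs:
            raise ConfigError(f"n_cpgs mismatch: cohort {c.cohort_id} has {c.n_cpgs}, expected {n_cpgs}")

    master = np.random.default_rng(np.random.SeedSequence([abs(cfg.seed) for cfg in configs]))
    n_causal = [int(round(c.frac_causal * n_cpgs)) for c in configs]
    n_shared = int(round(shared_truth_frac * min(n_causal)))
    shared_idx, shared_group = _choose_causal(master, n_cpgs, n_shared)
    remaining = np.setdiff1d(np.arange(n_cpgs), shared_idx, assume_unique=False)
    pool = remaining[master.permutation(len(remaining))]
    cursor = 0
    # shared signs: one draw per run/singleton group so planted regions are
    # directionally coherent (drawn from the first cohort's distribution)
    n_groups = int(shared_group.max()) + 1 if n_shared else 0
    group_sign = np.sign(master.normal(configs[0].effect_mean, configs[0].effect_sd, size=n_groups))
    group_sign[group_sign == 0] = 1.0
    shared_sign = group_sign[shared_group] if n_shared else np.array([])
    # divergent CpGs: a master-level subset of the shared *scattered* causal
    # CpGs (run members keep a coherent direction so planted regions survive)
    frac_div = configs[0].frac_sex_divergent
    n_div = int(round(frac_div * n_shared))
    if n_shared:
        counts = np.bincount(shared_group)
        singleton_pos = np.where(counts[shared_group] == 1)[0]
    else:
        singleton_pos = np.array([], dtype=int)
    n_div = min(n_div, len(singleton_pos))
    div_pos = (
        master.choice(singleton_pos, size=n_div, replace=False) if n_div else np.array([], dtype=int)
    )

    results = []
    for cfg, n_c in zip(configs, n_causal):
        n_private = n_c - n_shared
        if cursor + n_private > len(pool):
            raise ConfigError("not enough CpGs for disjoint cohort-private causal sets")
        private_idx = np.sort(pool[cursor : cursor + n_private])
        cursor += n_private
        rng_c = np.random.default_rng(np.random.SeedSequence([abs(cfg.seed), 17]))
        mag_shared = np.abs(rng_c.normal(cfg.effect_mean, cfg.effect_sd, size=n_shared))
        eff_shared = shared_sign * mag_shared * cfg.effect_attenuation
        eff_private = rng_c.normal(cfg.effect_mean, cfg.effect_sd, size=n_private) * cfg.effect_attenuation
        causal_idx = np.concatenate([shared_idx, private_idx])
        effects = np.concatenate([eff_shared, eff_private])
        order = np.argsort(causal_idx)
        # positions of divergent shared CpGs inside the ordered causal vector
        div_cpgs = set(shared_idx[div_pos])
        causal_sorted = causal_idx[order]
        div_positions = np.array(
            [i for i, cpg in enumerate(causal_sorted) if cpg in div_cpgs], dtype=int
        )
        planted = _effects_frame(n_cpgs, causal_sorted, effects[order], div_positions)
        results.append(generate_cohort(cfg, planted=planted))
    return results


# ---------------------------------------------------------------------------
# network data
# ---------------------------------------------------------------------------

def build_precision_matrix(spec: PrecisionSpec, seed: int = 0) -> np.ndarray:
    """Unit-diagonal precision matrix whose off-diagonals give the requested
    partial correlations (rho_ij = -Theta_ij on the unit diagonal)."""
    spec.validate()
    p = spec.n_nodes
    rho = spec.edge_strength
    theta = np.eye(p)
    if spec.structure == "chain":
        for i in range(p - 1):
            theta[i, i + 1] = theta[i + 1, i] = -rho
    elif spec.structure == "star":
        for j in range(1, p):
            theta[0, j] = theta[j, 0] = -rho
    else:  # random-sparse: Erdos-Renyi with expected degree 2
        rng = np.random.default_rng(seed)
        prob = min(1.0, 2.0 / max(p - 1, 1))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.uniform() < prob:
                    theta[i, j] = theta[j, i] = -rho
    eigmin = np.linalg.eigvalsh(theta).min()
    if eigmin <= 1e-10:
        raise ConfigError(
            f"implied precision matrix not positive definite "
            f"(min eigenvalue {eigmin:.3g}) for structure={spec.structure}, "
            f"edge_strength={rho}, n_nodes={p}"
        )
    return theta


def _stratum_rng(seed: int, spec: PrecisionSpec) -> np.random.Generator:
    # derived from the structural fields only, so structurally identical specs
    # reproduce the same draw regardless of the stratum label
    code = _STRUCTURES.index(spec.structure)
    return np.random.default_rng(
        np.random.SeedSequence([abs(seed), code, int(abs(spec.edge_strength) * 1e9), spec.n_nodes])
    )


def generate_ggm_data(
    spec_f: PrecisionSpec,
    spec_m: PrecisionSpec,
    n_per_stratum: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Zero-mean multivariate-normal M-value data for the two sex strata.

    Returns ``(data_female, data_male, truth)`` where each data frame is
    samples x nodes and ``truth`` maps stratum -> binary adjacency DataFrame
    (the nonzero off-diagonal pattern of the planted precision matrix).
    """
    if spec_f.n_nodes != spec_m.n_nodes:
        raise ConfigError("both strata must have the same n_nodes")
    node_ids = [f"cg{i:08d}" for i in range(spec_f.n_nodes)]
    out = []
    truth: dict[str, pd.DataFrame] = {}
    for label, spec in (("female", spec_f), ("male", spec_m)):
        theta = build_precision_matrix(spec, seed=seed)
        sigma = np.linalg.inv(theta)
        chol = np.linalg.cholesky(sigma)
        rng = _stratum_rng(seed, spec)
        z = rng.standard_normal(size=(n_per_stratum, spec.n_nodes))
        data = z @ chol.T
        out.append(
            pd.DataFrame(data, columns=node_ids, index=[f"{label[0]}{i:05d}" for i in range(n_per_stratum)])
        )
        adj = (np.abs(theta - np.diag(np.diag(theta))) > 1e-12).astype(int)
        truth[label] = pd.DataFrame(adj, index=node_ids, columns=node_ids)
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------

def generate_prs(
    samples: pd.DataFrame,
    correlation_with_outcome: float = 0.0,
    seed: int = 0,
    outcome: str = "FEV1",
    spiro_outcome: str = "FEV1_FVC",
) -> pd.DataFrame:
    """Standardised PRS columns with a requested population correlation.

    ``prs_asthma`` targets ``outcome`` and ``prs_spiro`` targets
    ``spiro_outcome``, both built as ``rho * z(outcome) + sqrt(1-rho^2) * eps``
    and re-standardised, which attains the requested population correlation.
    """
    if len(samples) == 0:
        raise ValueError("sample table is empty")
    if abs(correlation_with_outcome) >= 1.0:
        raise ValueError(f"|correlation| must be < 1, got {correlation_with_outcome}")
    rng = np.random.default_rng(seed)
    rho = correlation_with_outcome
    out = {"sample_id": samples["sample_id"].to_numpy()}
    for col, target in (("prs_asthma", outcome), ("prs_spiro", spiro_outcome)):
        y = samples[target].to_numpy(dtype=float)
        z = (y - np.nanmean(y)) / np.nanstd(y)
        score = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(samples))
        out[col] = (score - score.mean()) / score.std()
    return pd.DataFrame(out)
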