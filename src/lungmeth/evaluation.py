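"""Recovery and calibration benchmarks against planted synthetic truth.

Every function here simulates a study condition with :mod:`lungmeth.synthdata`,
runs the corresponding pipeline stage, and scores the result against the
planted truth or an independent closed-form oracle (ordinary least squares,
hand-computed pooling formulas, direct enumeration).  The oracles never call
the code paths they check.

These benchmarks back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ewas, ggmnet, metaconsist, methio, sexdiff, synthdata

OUTCOME = "FEV1"


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def ols_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Textbook simple-regression slope, SE and two-sided t-test p-value."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return slope, se, max(p, np.finfo(float).tiny)


def ols_scan(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-CpG simple OLS: M is (K, n).  Independent oracle for
    the robust scan (no shared code path)."""
    n = M.shape[1]
    xc = M - M.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=1)
    slope = (xc @ yc) / sxx
    resid = yc[None, :] - slope[:, None] * xc
    sigma2 = (resid * resid).sum(axis=1) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = slope / se
    p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), np.finfo(float).tiny, 1.0)
    return slope, se, p


def pooled_oracle(effects: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Hand formula sum(w b)/sum(w), 1/sqrt(sum w) with w = 1/se^2 (pure python loop)."""
    sw = swb = 0.0
    for b, s in zip(effects, ses):
        w = 1.0 / (s * s)
        sw += w
        swb += w * b
    return swb / sw, (1.0 / sw) ** 0.5


# ---------------------------------------------------------------------------
# benchmark 1: meta pooling vs the hand formula
# ---------------------------------------------------------------------------

def meta_oracle_max_error(n_cases: int = 1000, seed: int = 0) -> float:
    """Max |difference| between the package pooling and the hand formula
    over random small meta problems (effect and SE both compared)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        k = int(rng.integers(1, 6))
        b = rng.normal(0, 2, size=k)
        s = rng.uniform(0.05, 3.0, size=k)
        eff, se, _, _ = metaconsist.inverse_variance_meta(b, s)
        eff0, se0 = pooled_oracle(b, s)
        worst = max(worst, abs(eff - eff0), abs(se - se0))
    return worst


# ---------------------------------------------------------------------------
# benchmark 2: null three-study consistency rate
# ---------------------------------------------------------------------------

def null_consistency_rate(n_triples: int = 3_000_000, seed: int = 0) -> dict:
    """Fraction of null CpG-triples with p < 0.05 in all three studies and a
    fully consistent sign, scored through the package's direction machinery.

    Expectation under the null: 2 x 0.025^3 ~ 3.125e-5.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_triples, 3))
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_disc = (p < 0.05).all(axis=1)
    # run only the discovery survivors through the string machinery
    symbols = metaconsist.direction_symbols(z[all_disc], np.ones_like(z[all_disc], dtype=bool))
    directions = pd.Series(metaconsist.join_directions(symbols)) if all_disc.any() else pd.Series(dtype=str)
    consistent = metaconsist.consistent_mask(directions, "all_studies") if len(directions) else np.array([])
    count = int(np.sum(consistent))
    rate = count / n_triples
    expected = 2.0 * 0.025**3
    mc_se = float(np.sqrt(expected * (1 - expected) / n_triples))
    return {"rate": rate, "expected": expected, "mc_se": mc_se, "count": count, "n": n_triples}


# ---------------------------------------------------------------------------
# benchmark 3: FDR control of the null scan
# ---------------------------------------------------------------------------

def null_scan_fdr(
    n_replicates: int = 200,
    n_cpgs: int = 5000,
    n_samples: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FDR of the BH threshold on global-null robust EWAS scans.

    Under the global null every rejection is false, so the per-replicate
    false-discovery proportion is 1 when any CpG passes and 0 otherwise.
    """
    fdps = np.empty(n_replicates)
    for rep in range(n_replicates):
        cfg = synthdata.CohortConfig(
            cohort_id="NULL", n_samples=n_samples, n_cpgs=n_cpgs,
            frac_causal=0.0, seed=seed * 100_000 + rep,
        )
        beta, samples, _ = synthdata.generate_cohort(cfg)
        scan = ewas.run_ewas(methio.beta_to_m(beta), samples, OUTCOME, covariates=[])
        n_rej = int((scan["fdr"] < alpha).sum())
        fdps[rep] = 1.0 if n_rej > 0 else 0.0
    fdr_hat = float(fdps.mean())
    mc_se = float(fdps.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    return {"fdr": fdr_hat, "mc_se": mc_se, "alpha": alpha,
            "n_replicates": n_replicates, "n_cpgs": n_cpgs, "n_samples": n_samples}


# ---------------------------------------------------------------------------
# benchmark 4: robust vs OLS under contamination
# ---------------------------------------------------------------------------

def robust_vs_ols(
    n_replicates: int = 200,
    n_samples: int = 500,
    outlier_frac: float = 0.10,
    true_slope: float = 1.0,
    seed: int = 0,
) -> dict:
    """Share of replicates where the robust slope beats OLS in absolute error
    under gross y-contamination, and the clean-data relative agreement.

    Contamination is gross on the unit-residual scale (20-50 sigma, random
    sign): the bisquare estimator rejects such points outright while the OLS
    slope variance inflates by two orders of magnitude.
    """
    rng = np.random.default_rng(seed)
    wins = 0
    clean_rel = np.empty(n_replicates)
    for rep in range(n_replicates):
        x = rng.normal(size=n_samples)
        eps = rng.normal(size=n_samples)
        y_clean = 1.0 + true_slope * x + eps
        X = np.column_stack([np.ones(n_samples), x])
        # clean data: robust vs OLS agreement
        ols_b = ols_slope(y_clean, x)[0]
        rob_b = ewas.robust_fit(y_clean, X).coef[1]
        clean_rel[rep] = abs(rob_b - ols_b) / abs(ols_b)
        # contaminated data: who lands closer to the truth?
        y = y_clean.copy()
        n_out = int(outlier_frac * n_samples)
        pick = rng.choice(n_samples, size=n_out, replace=False)
        y[pick] += rng.choice([-1.0, 1.0], size=n_out) * rng.uniform(20, 50, size=n_out)
        ols_bc = ols_slope(y, x)[0]
        rob_bc = ewas.robust_fit(y, X).coef[1]
        if abs(rob_bc - true_slope) < abs(ols_bc - true_slope):
            wins += 1
    return {
        "win_frac": wins / n_replicates,
        "clean_mean_rel_diff": float(clean_rel.mean()),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# benchmark 5: planted-effect recovery through the full meta pipeline
# ---------------------------------------------------------------------------

def _scan_tables(triples, covariates, robust=True):
    tables = {}
    for beta, samples, _ in triples:
        cid = str(samples["cohort_id"].iloc[0])
        M = methio.beta_to_m(beta)
        covs = list(covariates)
        if "age" in covs and samples["age"].std() == 0:
            covs[covs.index("age")] = "gestational_age"  # birth cohort
        if robust:
            tables[cid] = ewas.run_ewas(M, samples, OUTCOME, covs)
        else:
            slope, se, p = ols_scan(M.to_numpy(), samples[OUTCOME].to_numpy(dtype=float))
            tables[cid] = pd.DataFrame(
                {
                    "cpg_id": M.index, "outcome": OUTCOME, "cohort": cid, "stratum": "all",
                    "n": len(samples), "effect": slope, "se": se, "p": p, "fdr": ewas.bh_fdr(p),
                }
            )
    return tables


def planted_meta_recovery(
    n_cpgs: int = 2000,
    frac_causal: float = 0.05,
    effect_mean: float = 0.5,
    seed: int = 0,
    fdr: float = 0.05,
    n_replicates: int = 6,
) -> dict:
    """Full meta pipeline on the default three-cohort study condition.

    Reports the mean pooled-estimate bias over planted causal CpGs, relative
    to the inverse-variance combination of the cohort-level planted effects
    (weights from the fitted SEs), plus the all-studies-tier sensitivity of
    the robust pipeline and of an independent per-CpG OLS oracle pushed
    through the same meta and retention logic.  Because all per-CpG errors in
    one study realisation share the same outcome vector, the bias of a single
    realisation is noisy; results are averaged over ``n_replicates``
    independent study draws.
    """
    reps = [
        _planted_meta_recovery_once(n_cpgs, frac_causal, seed * 37 + r, fdr)
        for r in range(n_replicates)
    ]
    return {
        "bias_pct": float(np.mean([r["bias_pct"] for r in reps])),
        "sensitivity_robust": float(np.mean([r["sensitivity_robust"] for r in reps])),
        "sensitivity_ols_oracle": float(np.mean([r["sensitivity_ols_oracle"] for r in reps])),
        "n_causal": int(sum(r["n_causal"] for r in reps)),
        "n_cpgs": n_cpgs,
        "n_replicates": n_replicates,
    }


def _planted_meta_recovery_once(
    n_cpgs: int,
    frac_causal: float,
    seed: int,
    fdr: float,
) -> dict:
    configs = synthdata.default_study_configs(
        n_cpgs=n_cpgs, frac_causal=frac_causal, frac_sex_divergent=0.0, seed=seed,
    )
    triples = synthdata.generate_multi_cohort(configs, shared_truth_frac=1.0)
    truth = triples[0][2]
    causal = set(truth.loc[truth["is_causal"] & (truth["outcome"] == OUTCOME), "cpg_id"])

    tables_rob = _scan_tables(triples, covariates=["sex", "age"], robust=True)
    tables_ols = _scan_tables(triples, covariates=["sex", "age"], robust=False)

    def retain(tables) -> tuple[pd.DataFrame, float]:
        meta = metaconsist.run_meta(tables, discovery_p=0.05)
        kept = metaconsist.consistency_filter(meta, "all_studies", fdr_threshold=fdr)
        return meta, len(causal & set(kept["cpg_id"])) / len(causal)

    meta_rob, sens_rob = retain(tables_rob)
    _, sens_ols = retain(tables_ols)

    # pooled truth per causal CpG: IVW combination of cohort-level planted
    # effects using each cohort scan's weights
    cids = [str(t[1]["cohort_id"].iloc[0]) for t in triples]
    truth_by_cohort = {
        str(t[1]["cohort_id"].iloc[0]): t[2][t[2]["outcome"] == OUTCOME].set_index("cpg_id")["effect_all"]
        for t in triples
    }
    scans_by_cpg = {cid: tables_rob[cid].set_index("cpg_id") for cid in cids}
    est = meta_rob.set_index("cpg_id")
    biases, truths = [], []
    for cpg in sorted(causal):
        if cpg not in est.index:
            continue
        ws, bs = [], []
        for cid in cids:
            row = scans_by_cpg[cid]
            if cpg in row.index:
                ws.append(1.0 / row.at[cpg, "se"] ** 2)
                bs.append(truth_by_cohort[cid].at[cpg])
        t_pooled = float(np.dot(ws, bs) / np.sum(ws))
        biases.append(est.at[cpg, "effect"] - t_pooled)
        truths.append(t_pooled)
    bias_pct = 100.0 * float(np.mean(biases)) / float(np.mean(np.abs(truths)))
    return {
        "bias_pct": bias_pct,
        "sensitivity_robust": sens_rob,
        "sensitivity_ols_oracle": sens_ols,
        "n_causal": len(causal),
        "n_cpgs": n_cpgs,
    }


# ---------------------------------------------------------------------------
# benchmark 6: GGM edge recovery and null sparsity
# ---------------------------------------------------------------------------

def _edge_f1(adj_est: np.ndarray, adj_true: np.ndarray) -> float:
    iu = np.triu_indices(adj_true.shape[0], k=1)
    e = adj_est[iu].astype(bool)
    t = adj_true[iu].astype(bool)
    tp = int((e & t).sum())
    fp = int((e & ~t).sum())
    fn = int((~e & t).sum())
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def ggm_chain_recovery(
    n_replicates: int = 5,
    n_nodes: int = 20,
    n_samples: int = 2000,
    edge_strength: float = 0.4,
    seed: int = 0,
) -> dict:
    """Edge-recovery F1 on chain-structured data (planted-truth oracle)."""
    f1s = []
    for rep in range(n_replicates):
        spec = synthdata.PrecisionSpec(n_nodes, "chain", edge_strength, "female")
        spec_m = synthdata.PrecisionSpec(n_nodes, "chain", edge_strength, "male")
        data_f, _, truth = synthdata.generate_ggm_data(spec, spec_m, n_samples, seed=seed * 1000 + rep)
        net = ggmnet.estimate_ggm(data_f, seed=seed + rep)
        f1s.append(_edge_f1(net.adjacency.to_numpy(), truth["female"].to_numpy()))
    return {"f1_min": float(min(f1s)), "f1_mean": float(np.mean(f1s)), "n_replicates": n_replicates}


def ggm_null_sparsity(
    n_replicates: int = 20,
    n_nodes: int = 20,
    n_samples: int = 2000,
    seed: int = 0,
) -> dict:
    """Edge counts of the selected graph on independent standard normals."""
    counts = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 1000 + rep)
        data = pd.DataFrame(rng.standard_normal((n_samples, n_nodes)))
        net = ggmnet.estimate_ggm(data, seed=seed + rep)
        counts.append(net.n_edges)
    counts = np.asarray(counts)
    return {
        "frac_at_most_one_edge": float((counts <= 1).mean()),
        "mean_edges": float(counts.mean()),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# benchmark 7: differential hub recovery
# ---------------------------------------------------------------------------

def hub_recovery(
    n_replicates: int = 50,
    n_nodes: int = 20,
    n_samples: int = 2000,
    star_strength: float = 0.2,
    chain_strength: float = 0.4,
    diff_threshold: float = 0.20,
    seed: int = 0,
) -> dict:
    """Planted female star hub (node 0) vs male chain: how often does the
    planted node's hub-score difference exceed the threshold?"""
    hits = 0
    diffs = []
    for rep in range(n_replicates):
        spec_f = synthdata.PrecisionSpec(n_nodes, "star", star_strength, "female")
        spec_m = synthdata.PrecisionSpec(n_nodes, "chain", chain_strength, "male")
        data_f, data_m, _ = synthdata.generate_ggm_data(spec_f, spec_m, n_samples, seed=seed * 1000 + rep)
        net_f = ggmnet.estimate_ggm(data_f, seed=seed + rep)
        net_m = ggmnet.estimate_ggm(data_m, seed=seed + rep)
        table = ggmnet.differential_hubs(net_f, net_m, diff_threshold)
        planted = table.set_index("cpg_id").loc[data_f.columns[0]]
        diffs.append(float(planted["diff"]))
        hits += bool(planted["flagged"])
    return {
        "recovery_frac": hits / n_replicates,
        "mean_diff": float(np.mean(diffs)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# benchmark 8: sex-divergent DMP recovery
# ---------------------------------------------------------------------------

def divergent_recovery(
    n_cpgs: int = 1000,
    frac_causal: float = 0.05,
    frac_sex_divergent: float = 0.5,
    n_per_stratum: int = 2000,
    seed: int = 0,
) -> dict:
    """Sensitivity and false-discovery proportion for planted sex-divergent
    CpGs recovered through the stratified meta pipeline."""
    configs = [
        synthdata.CohortConfig(
            cohort_id=f"S{i}", n_samples=2 * n_per_stratum, n_cpgs=n_cpgs,
            frac_causal=frac_causal, frac_sex_divergent=frac_sex_divergent,
            frac_female=0.5, seed=seed * 1000 + i,
        )
        for i in range(3)
    ]
    triples = synthdata.generate_multi_cohort(configs, shared_truth_frac=1.0)
    truth = triples[0][2]
    planted = set(truth.loc[truth["is_divergent"] & (truth["outcome"] == OUTCOME), "cpg_id"])
    metas = {}
    for stratum in ("F", "M"):
        tables = {
            str(s["cohort_id"].iloc[0]): ewas.run_ewas(
                methio.beta_to_m(b), s, OUTCOME, ["age"], stratum=stratum
            )
            for b, s, _ in triples
        }
        metas[stratum] = metaconsist.run_meta(tables, discovery_p=0.05)
    div = sexdiff.divergent_dmps(metas["F"], metas["M"], fdr_threshold=0.05)
    found = set(div["cpg_id"])
    sens = len(planted & found) / len(planted) if planted else float("nan")
    fdp = len(found - planted) / len(found) if found else 0.0
    return {"sensitivity": sens, "fdp": fdp, "n_planted": len(planted), "n_found": len(found)}
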