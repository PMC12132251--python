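"""Sparse Gaussian graphical models and differential hub scoring by sex.

The divergent-DMP set (or any CpG list) is residualised against covariates,
and a graphical-lasso model is estimated per sex stratum along a
regularisation path.  Model selection is EBIC (gamma = 0.5) by default —
consistent for sparse graphs and near-empty under independence — with StARS
(20 subsamples of floor(0.8 n), instability threshold 0.1) and a fixed
lambda as alternatives; at these subsampling constants StARS admits small
unstable edge sets under the null, so it is offered but not the default.  Edges are the nonzero off-diagonal entries of the
selected precision matrix Theta, reported as partial correlations
``rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)``.

A node's **hub score** is its eigenvector centrality on the
|partial correlation|-weighted adjacency, normalised so the maximum score in
a nonempty network is 1 (for a symmetric matrix the HITS hub and authority
vectors coincide with this).  Differential hubs are nodes whose female/male
hub-score difference exceeds a threshold (default 0.20).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from . import ewas as _ewas

logger = logging.getLogger(__name__)

#: default regularisation path: 10 log-spaced values from lambda_max down to
#: LAMBDA_MIN_RATIO * lambda_max.  The floor keeps the path inside the
#: sparsistent regime for the planted structures this package simulates.
N_LAMBDA = 10
LAMBDA_MIN_RATIO = 0.25

STARS_SUBSAMPLES = 20
STARS_SUBSAMPLE_FRAC = 0.8
STARS_THRESHOLD = 0.1
EBIC_GAMMA = 0.5

EDGE_EPS = 1e-8


@dataclass
class GGMNetwork:
    """Estimated sparse partial-correlation network for one stratum."""

    node_ids: list[str]
    partial_corr: pd.DataFrame
    adjacency: pd.DataFrame
    precision: np.ndarray
    lambda_path: np.ndarray
    lambda_selected: float
    selection_method: str
    instability: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def edge_list(self) -> pd.DataFrame:
        """Long-format edges: node_i, node_j, partial_corr (i < j)."""
        pc = self.partial_corr.to_numpy()
        adj = self.adjacency.to_numpy()
        rows = []
        for i in range(len(self.node_ids)):
            for j in range(i + 1, len(self.node_ids)):
                if adj[i, j]:
                    rows.append((self.node_ids[i], self.node_ids[j], pc[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "partial_corr"])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for _, (i, j, w) in self.edge_list().iterrows():
            g.add_edge(i, j, weight=float(w))
        return g


# ---------------------------------------------------------------------------
# residualisation
# ---------------------------------------------------------------------------

def residualize(
    meth: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str],
) -> pd.DataFrame:
    """Least-squares residuals of each CpG's M-values on the covariates.

    Input is CpG x sample; output is sample x CpG (ready for network
    estimation), with column means ~0.  Rank-deficient covariate designs
    raise, naming the collinear columns.
    """
    common = [s for s in meth.columns if s in set(samples["sample_id"])]
    sub = samples.set_index("sample_id").loc[common].reset_index()
    X, _ = _ewas.build_design(sub, covariates)
    Y = meth[common].to_numpy(dtype=float).T  # (n, p_cpgs)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=common, columns=meth.index)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _standardize(data: np.ndarray) -> np.ndarray:
    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (data - data.mean(axis=0)) / sd


def _glasso_precision(S: np.ndarray, alpha: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, prec = graphical_lasso(S, alpha=alpha, max_iter=200, tol=1e-5)
        except FloatingPointError:
            # fall back to a slightly stronger penalty on numerical failure
            _, prec = graphical_lasso(S, alpha=alpha * 1.05 + 1e-4, max_iter=200, tol=1e-4)
    return prec


def _adjacency_from_precision(prec: np.ndarray) -> np.ndarray:
    off = np.abs(prec.copy())
    np.fill_diagonal(off, 0.0)
    return (off > EDGE_EPS).astype(int)


def default_lambda_path(S: np.ndarray) -> np.ndarray:
    lam_max = np.abs(S - np.diag(np.diag(S))).max()
    lam_max = max(lam_max, 1e-3)
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, N_LAMBDA)


def _ebic_score(prec: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(S @ prec))
    n_edges = _adjacency_from_precision(prec).sum() / 2
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def estimate_ggm(
    data: pd.DataFrame,
    lambda_path: np.ndarray | None = None,
    selection: str = "ebic",
    stars_subsamples: int = STARS_SUBSAMPLES,
    stars_threshold: float = STARS_THRESHOLD,
    subsample_frac: float = STARS_SUBSAMPLE_FRAC,
    ebic_gamma: float = EBIC_GAMMA,
    fixed_lambda: float | None = None,
    seed: int = 0,
) -> GGMNetwork:
    """Graphical-lasso network over a regularisation path with model selection.

    ``data`` is samples x nodes; columns are standardised internally and the
    model is fit on the correlation matrix.  ``selection`` is one of
    ``ebic`` (default), ``stars`` or ``fixed`` (requires ``fixed_lambda``).
    ``p > n`` is allowed (the lasso regularises) with a warning.
    """
    node_ids = [str(c) for c in data.columns]
    X = data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in network input data")
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError(f"need n >= 3 and p >= 2, got n={n}, p={p}")
    if p > n:
        logger.warning("estimate_ggm: p=%d > n=%d; relying on regularisation", p, n)
    Xs = _standardize(X)
    S = np.corrcoef(Xs, rowvar=False)
    path = default_lambda_path(S) if lambda_path is None else np.asarray(lambda_path, dtype=float)
    path = np.sort(path)[::-1]  # strongest penalty first

    instability = None
    if selection == "fixed":
        if fixed_lambda is None:
            raise ValueError("selection='fixed' requires fixed_lambda")
        lam_sel = float(fixed_lambda)
    elif selection == "ebic":
        scores = []
        for lam in path:
            prec = _glasso_precision(S, lam)
            scores.append(_ebic_score(prec, S, n, ebic_gamma))
        lam_sel = float(path[int(np.argmin(scores))])
    elif selection == "stars":
        rng = np.random.default_rng(seed)
        b = int(np.floor(subsample_frac * n))
        freq = np.zeros((len(path), p, p))
        for _ in range(stars_subsamples):
            idx = rng.choice(n, size=b, replace=False)
            Sb = np.corrcoef(Xs[idx], rowvar=False)
            for li, lam in enumerate(path):
                freq[li] += _adjacency_from_precision(_glasso_precision(Sb, lam))
        theta_hat = freq / stars_subsamples
        xi = 2.0 * theta_hat * (1.0 - theta_hat)
        iu = np.triu_indices(p, k=1)
        instability = xi[:, iu[0], iu[1]].mean(axis=1)
        # monotonise from the sparse end, then take the densest lambda whose
        # monotonised instability stays below the threshold
        mono = np.maximum.accumulate(instability)
        ok = np.where(mono <= stars_threshold)[0]
        lam_sel = float(path[ok[-1]]) if ok.size else float(path[0])
    else:
        raise ValueError(f"unknown selection method {selection!r}")

    prec = _glasso_precision(S, lam_sel)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc = (pc + pc.T) / 2.0
    adj = _adjacency_from_precision(prec)
    pc = pc * adj  # adjacency nonzero <=> partial correlation nonzero
    net = GGMNetwork(
        node_ids=node_ids,
        partial_corr=pd.DataFrame(pc, index=node_ids, columns=node_ids),
        adjacency=pd.DataFrame(adj, index=node_ids, columns=node_ids),
        precision=prec,
        lambda_path=path,
        lambda_selected=lam_sel,
        selection_method=selection,
        instability=instability,
    )
    logger.info(
        "estimate_ggm[%s]: lambda=%.4g, %d edge(s) on %d node(s)",
        selection, lam_sel, net.n_edges, p,
    )
    return net


# ---------------------------------------------------------------------------
# hub scores
# ---------------------------------------------------------------------------

def hub_scores(net: GGMNetwork) -> pd.Series:
    """Eigenvector/HITS hub centrality on |partial correlation| weights.

    Principal eigenvector of the weighted adjacency, taken elementwise
    absolute and normalised to a maximum of 1; an edgeless network scores
    every node 0.
    """
    W = np.abs(net.partial_corr.to_numpy())
    if W.sum() == 0:
        return pd.Series(0.0, index=net.node_ids, name="hub")
    vals, vecs = np.linalg.eigh(W)
    v = np.abs(vecs[:, int(np.argmax(vals))])
    v = v / v.max()
    # suppress numerically-zero entries (isolated components score exactly 0)
    v[v < 1e-12] = 0.0
    return pd.Series(v, index=net.node_ids, name="hub")


def differential_hubs(
    net_f: GGMNetwork,
    net_m: GGMNetwork,
    diff_threshold: float = 0.20,
) -> pd.DataFrame:
    """Hub table with per-node female/male scores, |difference| and a flag.

    Requires identical node sets (error lists the symmetric difference);
    returns the full table sorted by descending difference, with ``flagged``
    True where the difference exceeds ``diff_threshold``.
    """
    if set(net_f.node_ids) != set(net_m.node_ids):
        diff = set(net_f.node_ids) ^ set(net_m.node_ids)
        raise ValueError(f"node sets differ between strata: {sorted(diff)[:10]}")
    hub_f = hub_scores(net_f)
    hub_m = hub_scores(net_m).reindex(hub_f.index)
    table = pd.DataFrame(
        {
            "cpg_id": hub_f.index,
            "hub_f": hub_f.to_numpy(),
            "hub_m": hub_m.to_numpy(),
            "diff": np.abs(hub_f.to_numpy() - hub_m.to_numpy()),
        }
    )
    table["flagged"] = table["diff"] > diff_threshold
    table = table.sort_values("diff", ascending=False, kind="stable").reset_index(drop=True)
    logger.info("differential_hubs: %d / %d node(s) above %.2f", int(table["flagged"].sum()), len(table), diff_threshold)
    return table


def write_graphml(net: GGMNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)
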