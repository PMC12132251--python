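"""Residualisation, graphical-lasso estimation and hub scoring."""

import numpy as np
import pandas as pd
import pytest

from lungmeth import ggmnet, synthdata
from lungmeth.evaluation import _edge_f1


def make_net(pc: np.ndarray, ids=None) -> ggmnet.GGMNetwork:
    ids = ids or [f"n{i}" for i in range(pc.shape[0])]
    adj = (np.abs(pc) > 0).astype(int)
    return ggmnet.GGMNetwork(
        node_ids=ids,
        partial_corr=pd.DataFrame(pc, index=ids, columns=ids),
        adjacency=pd.DataFrame(adj, index=ids, columns=ids),
        precision=np.eye(pc.shape[0]),
        lambda_path=np.array([0.1]),
        lambda_selected=0.1,
        selection_method="fixed",
    )


@pytest.fixture(scope="module")
def data():
    cfg = synthdata.CohortConfig(cohort_id="G", n_samples=150, n_cpgs=30, seed=3)
    beta, samples, _ = synthdata.generate_cohort(cfg)
    from lungmeth import methio

    return methio.beta_to_m(beta), samples


class TestResidualize:

    def test_intercept_only_centres(self, data):
        m, samples = data
        resid = ggmnet.residualize(m, samples, [])
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-10)
        centred = m[resid.index].to_numpy().T - m[resid.index].to_numpy().T.mean(axis=0)
        np.testing.assert_allclose(resid.to_numpy(), centred, atol=1e-10)

    def test_exact_covariate_dependence_gives_zero_residuals(self, data):
        m, samples = data
        m2 = m.copy()
        age = samples.set_index("sample_id").loc[m.columns, "age"]
        m2.iloc[0] = 2.0 + 0.5 * age.to_numpy()
        resid = ggmnet.residualize(m2, samples, ["age"])
        assert np.linalg.norm(resid.iloc[:, 0]) < 1e-8

    def test_residuals_orthogonal_to_covariates(self, data):
        m, samples = data
        resid = ggmnet.residualize(m, samples, ["age", "height"])
        sub = samples.set_index("sample_id").loc[resid.index]
        for cov in ("age", "height"):
            corr = np.corrcoef(sub[cov], resid.to_numpy(), rowvar=False)[0, 1:]
            assert np.abs(corr).max() < 1e-8

    def test_rank_deficiency_raises(self, data):
        m, samples = data
        dup = samples.assign(age2=samples["age"])
        from lungmeth import ewas

        with pytest.raises(ewas.RankDeficientError):
            ggmnet.residualize(m, dup, ["age", "age2"])


class TestEstimateGgm:
    def test_chain_recovery_f1(self):
        spec_f = synthdata.PrecisionSpec(20, "chain", 0.4, "female")
        spec_m = synthdata.PrecisionSpec(20, "chain", 0.4, "male")
        data, _, truth = synthdata.generate_ggm_data(spec_f, spec_m, 2000, seed=5)
        net = ggmnet.estimate_ggm(data, seed=0)
        assert _edge_f1(net.adjacency.to_numpy(), truth["female"].to_numpy()) >= 0.8

    def test_partial_corr_map_matches_direct_inversion(self):
        """lambda -> 0 with n >> p: regularised estimate ~ inverted covariance."""
        spec_f = synthdata.PrecisionSpec(8, "chain", 0.4, "female")
        spec_m = synthdata.PrecisionSpec(8, "chain", 0.4, "male")
        data, _, _ = synthdata.generate_ggm_data(spec_f, spec_m, 4000, seed=6)
        net = ggmnet.estimate_ggm(data, selection="fixed", fixed_lambda=1e-4)
        prec = np.linalg.inv(np.corrcoef(data.to_numpy(), rowvar=False))
        d = np.sqrt(np.diag(prec))
        pc_direct = -prec / np.outer(d, d)
        np.fill_diagonal(pc_direct, 0.0)
        est = net.partial_corr.to_numpy()
        assert np.abs(est - pc_direct).max() < 0.02

    def test_duplicated_column_forces_edge(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 5))
        x[:, 4] = x[:, 3] + 1e-6 * rng.standard_normal(500)
        net = ggmnet.estimate_ggm(pd.DataFrame(x), selection="fixed", fixed_lambda=0.05)
        assert net.adjacency.iloc[3, 4] == 1

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(8)
        net = ggmnet.estimate_ggm(pd.DataFrame(rng.standard_normal((200, 10))), seed=0)
        pc = net.partial_corr.to_numpy()
        np.testing.assert_allclose(pc, pc.T, atol=1e-10)
        assert (np.diag(pc) == 0).all()
        assert ((net.adjacency.to_numpy() != 0) == (pc != 0)).all()

    def test_nonfinite_data_rejected(self):
        bad = pd.DataFrame(np.full((10, 3), np.nan))
        with pytest.raises(ValueError, match="finite"):
            ggmnet.estimate_ggm(bad)

    def test_p_greater_than_n_allowed(self):
        rng = np.random.default_rng(4)
        net = ggmnet.estimate_ggm(pd.DataFrame(rng.standard_normal((15, 25))), seed=0)
        assert net.partial_corr.shape == (25, 25)

    def test_stars_selection_runs(self):
        spec_f = synthdata.PrecisionSpec(10, "chain", 0.4, "female")
        spec_m = synthdata.PrecisionSpec(10, "chain", 0.4, "male")
        data, _, truth = synthdata.generate_ggm_data(spec_f, spec_m, 400, seed=7)
        net = ggmnet.estimate_ggm(data, selection="stars", stars_subsamples=8, seed=0)
        assert net.selection_method == "stars"
        assert net.instability is not None
        # the true chain edges dominate whatever extra edges StARS admits
        adj = net.adjacency.to_numpy()
        true_edges = sum(adj[i, i + 1] for i in range(9))
        assert true_edges >= 7


class TestHubScores:
    def test_star_center_scores_one(self):
        pc = np.zeros((5, 5))
        pc[0, 1:] = pc[1:, 0] = 0.3
        hubs = ggmnet.hub_scores(make_net(pc))
        assert hubs.iloc[0] == pytest.approx(1.0)
        leaves = hubs.iloc[1:]
        assert (leaves < 1).all()
        np.testing.assert_allclose(leaves, leaves.iloc[0])

    def test_empty_graph_all_zero(self):
        hubs = ggmnet.hub_scores(make_net(np.zeros((4, 4))))
        assert (hubs == 0).all()

    def test_complete_graph_all_one(self):
        pc = np.full((6, 6), 0.2)
        np.fill_diagonal(pc, 0.0)
        hubs = ggmnet.hub_scores(make_net(pc))
        np.testing.assert_allclose(hubs, 1.0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pc = rng.uniform(-0.3, 0.3, size=(7, 7))
        pc = (pc + pc.T) / 2
        np.fill_diagonal(pc, 0.0)
        hubs = ggmnet.hub_scores(make_net(pc))
        perm = rng.permutation(7)
        hubs_p = ggmnet.hub_scores(make_net(pc[np.ix_(perm, perm)]))
        np.testing.assert_allclose(hubs_p.to_numpy(), hubs.to_numpy()[perm], atol=1e-9)

    def test_isolated_component_scores_zero(self):
        pc = np.zeros((5, 5))
        pc[0, 1] = pc[1, 0] = 0.5  # dominant pair
        pc[2, 3] = pc[3, 2] = 0.1  # weaker, disconnected pair
        hubs = ggmnet.hub_scores(make_net(pc))
        assert hubs.iloc[0] == pytest.approx(1.0)
        assert hubs.iloc[2] == pytest.approx(0.0, abs=1e-9)
        assert hubs.iloc[4] == 0.0


class TestDifferentialHubs:
    def test_flagging_threshold(self):
        pc_f = np.zeros((5, 5))
        pc_f[0, 1:] = pc_f[1:, 0] = 0.3  # star: node 0 hub
        pc_m = np.zeros((5, 5))
        for i in range(4):
            pc_m[i, i + 1] = pc_m[i + 1, i] = 0.3  # chain
        table = ggmnet.differential_hubs(make_net(pc_f), make_net(pc_m), 0.20).set_index("cpg_id")
        assert bool(table.at["n0", "flagged"])

    def test_small_difference_not_flagged(self):
        pc = np.zeros((4, 4))
        pc[0, 1] = pc[1, 0] = 0.4
        f = make_net(pc)
        pc_m = pc * 0.9
        table = ggmnet.differential_hubs(f, make_net(pc_m), 0.20)
        # same topology, same hub pattern: differences stay tiny
        assert not table["flagged"].any()

    def test_identical_networks_zero_differences(self):
        rng = np.random.default_rng(5)
        pc = rng.uniform(-0.2, 0.2, size=(6, 6))
        pc = (pc + pc.T) / 2
        np.fill_diagonal(pc, 0.0)
        table = ggmnet.differential_hubs(make_net(pc), make_net(pc.copy()), 0.20)
        assert (table["diff"] == 0).all()
        assert not table["flagged"].any()

    def test_node_mismatch_listed(self):
        f = make_net(np.zeros((3, 3)), ids=["a", "b", "c"])
        m = make_net(np.zeros((3, 3)), ids=["a", "b", "d"])
        with pytest.raises(ValueError, match="c.*d|d.*c"):
            ggmnet.differential_hubs(f, m)


def test_graphml_round_trip(tmp_path):
    import networkx as nx

    pc = np.zeros((4, 4))
    pc[0, 1] = pc[1, 0] = 0.25
    net = make_net(pc)
    path = tmp_path / "net.graphml"
    ggmnet.write_graphml(net, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 4
    assert g.number_of_edges() == 1
    assert g["n0"]["n1"]["weight"] == pytest.approx(0.25)
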