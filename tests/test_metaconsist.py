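"""Fixed-effects pooling, direction strings, retention tiers and regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lungmeth import ewas, metaconsist
from lungmeth.evaluation import pooled_oracle


def make_scan(cohort, cpgs, effects, ses, ps=None, outcome="FEV1", stratum="all"):
    ps = ps if ps is not None else [0.01] * len(cpgs)
    return pd.DataFrame(
        {
            "cpg_id": cpgs, "outcome": outcome, "cohort": cohort, "stratum": stratum,
            "n": 100, "effect": effects, "se": ses, "p": ps,
            "fdr": ewas.bh_fdr(np.asarray(ps, dtype=float)),
        }
    )


class TestInverseVarianceMeta:
    def test_equal_weight_mean(self):
        eff, se, z, p = metaconsist.inverse_variance_meta([2, 2, 2], [1, 1, 1])
        assert eff == pytest.approx(2.0)
        assert se == pytest.approx(1 / np.sqrt(3))

    def test_symmetric_average(self):
        eff, se, _, _ = metaconsist.inverse_variance_meta([1, 3], [1, 1])
        assert eff == pytest.approx(2.0)
        assert se == pytest.approx(0.7071, abs=1e-4)

    def test_unequal_weights_hand_formula(self):
        # w = (1, 0.25): effect = (1*1 + 0.25*3) / 1.25 = 1.4
        eff, se, _, _ = metaconsist.inverse_variance_meta([1, 3], [1, 2])
        assert eff == pytest.approx(1.4)
        assert se == pytest.approx(0.8944, abs=1e-4)

    def test_missing_pairs_dropped(self):
        eff, se, _, _ = metaconsist.inverse_variance_meta([1.0, np.nan, 3.0], [1.0, 1.0, 2.0])
        assert eff == pytest.approx(1.4)

    def test_single_study_identity(self):
        eff, se, _, _ = metaconsist.inverse_variance_meta([0.7], [0.2])
        assert (eff, se) == (pytest.approx(0.7), pytest.approx(0.2))

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            metaconsist.inverse_variance_meta([np.nan], [np.nan])

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError, match="positive"):
            metaconsist.inverse_variance_meta([1.0], [0.0])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_hand_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 6))
        b = rng.normal(0, 2, size=k)
        s = rng.uniform(0.05, 3.0, size=k)
        eff, se, _, _ = metaconsist.inverse_variance_meta(b, s)
        eff0, se0 = pooled_oracle(b, s)
        assert eff == pytest.approx(eff0, abs=1e-10)
        assert se == pytest.approx(se0, abs=1e-10)

    def test_pooled_se_never_exceeds_best_study(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(1, 5))
            s = rng.uniform(0.05, 2.0, size=k)
            _, se, _, _ = metaconsist.inverse_variance_meta(rng.normal(size=k), s)
            assert se <= s.min() + 1e-12


class TestRunMeta:
    def test_direction_strings(self):
        tables = {
            "A": make_scan("A", ["c1", "c2"], [0.07, -0.09], [0.02, 0.02]),
            "B": make_scan("B", ["c1", "c2"], [0.03, -0.05], [0.02, 0.02]),
            "C": make_scan("C", ["c1", "c2"], [0.02, -0.02], [0.02, 0.02]),
        }
        meta = metaconsist.run_meta(tables).set_index("cpg_id")
        assert meta.at["c1", "direction"] == "+++"
        assert meta.at["c2", "direction"] == "---"
        assert (meta["n_studies"] == 3).all()

    def test_absent_cohort_symbol(self):
        tables = {
            "A": make_scan("A", ["c1"], [0.07], [0.02]),
            "B": make_scan("B", [], [], []),
            "C": make_scan("C", ["c1"], [0.02], [0.02]),
        }
        meta = metaconsist.run_meta(tables).set_index("cpg_id")
        assert meta.at["c1", "direction"] == "+?+"
        assert meta.at["c1", "n_studies"] == 2

    def test_single_contributing_study_identity(self):
        tables = {
            "A": make_scan("A", ["c1"], [0.5], [0.1]),
            "B": make_scan("B", [], [], []),
        }
        meta = metaconsist.run_meta(tables).set_index("cpg_id")
        assert meta.at["c1", "effect"] == pytest.approx(0.5)
        assert meta.at["c1", "se"] == pytest.approx(0.1)

    def test_discovery_threshold_gates_entry(self):
        tables = {
            "A": make_scan("A", ["c1", "c2"], [0.5, 0.5], [0.1, 0.1], ps=[0.2, 0.01]),
            "B": make_scan("B", ["c1", "c2"], [0.5, 0.5], [0.1, 0.1], ps=[0.3, 0.5]),
        }
        meta = metaconsist.run_meta(tables, discovery_p=0.05)
        assert list(meta["cpg_id"]) == ["c2"]

    def test_designated_discovery_cohort_mode(self):
        tables = {
            "A": make_scan("A", ["c1", "c2"], [0.5, 0.5], [0.1, 0.1], ps=[0.2, 0.01]),
            "B": make_scan("B", ["c1", "c2"], [0.5, 0.5], [0.1, 0.1], ps=[0.01, 0.5]),
        }
        meta = metaconsist.run_meta(tables, discovery_cohorts=["A"])
        assert list(meta["cpg_id"]) == ["c2"]

    def test_no_survivors_empty_with_warning(self, caplog):
        tables = {"A": make_scan("A", ["c1"], [0.5], [0.1], ps=[0.9])}
        meta = metaconsist.run_meta(tables)
        assert len(meta) == 0

    def test_pooled_values_match_per_cpg_operation(self):
        tables = {
            "A": make_scan("A", ["c1"], [1.0], [1.0]),
            "B": make_scan("B", ["c1"], [3.0], [2.0]),
        }
        meta = metaconsist.run_meta(tables).set_index("cpg_id")
        assert meta.at["c1", "effect"] == pytest.approx(1.4)
        assert meta.at["c1", "z"] == pytest.approx(meta.at["c1", "effect"] / meta.at["c1", "se"])


class TestConsistencyFilter:
    def _meta(self, rows):
        return pd.DataFrame(
            rows, columns=["cpg_id", "direction", "fdr"]
        ).assign(outcome="FEV1", stratum="all", effect=1.0)

    @pytest.mark.parametrize(
        "direction,fdr,in_all,in_two",
        [
            ("+++", 0.01, True, True),
            ("++?", 0.01, False, True),
            ("+++", 0.20, False, False),   # FDR threshold excludes
            ("++-", 0.01, False, True),    # disagreeing third: two_of_three only
            ("+--", 0.01, False, True),
            ("+?-", 0.01, False, False),   # only one sign on each side
            ("++0", 0.01, False, True),    # zero counts as disagreement
            ("000", 0.01, False, False),
            ("???", 0.01, False, False),
        ],
    )
    def test_tier_rules(self, direction, fdr, in_all, in_two):
        meta = self._meta([("c", direction, fdr)])
        assert bool(len(metaconsist.consistency_filter(meta, "all_studies"))) is in_all
        assert bool(len(metaconsist.consistency_filter(meta, "two_of_three"))) is in_two

    def test_all_studies_subset_of_two_of_three(self):
        rng = np.random.default_rng(0)
        symbols = np.array(list("+-0?"))
        rows = [
            ("c%d" % i, "".join(rng.choice(symbols, 3)), float(rng.uniform(0, 0.1)))
            for i in range(300)
        ]
        meta = self._meta(rows)
        tier_all = set(metaconsist.consistency_filter(meta, "all_studies")["cpg_id"])
        tier_two = set(metaconsist.consistency_filter(meta, "two_of_three")["cpg_id"])
        assert tier_all <= tier_two

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError, match="tier"):
            metaconsist.consistency_filter(self._meta([("c", "+++", 0.01)]), "bogus")


class TestMultiTraitOverlap:
    def test_enumerated_example(self):
        out = metaconsist.multi_trait_overlap({"A": {"c1", "c2"}, "B": {"c2"}, "C": {"c2", "c3"}})
        per = out["per_cpg"].set_index("cpg_id")
        assert per.at["c2", "n_traits"] == 3
        at_least = out["at_least"].set_index("k")["count"]
        assert at_least[3] == 1
        assert at_least[1] == 3

    def test_disjoint_sets(self):
        out = metaconsist.multi_trait_overlap({"A": {"c1"}, "B": {"c2"}})
        assert (out["per_cpg"]["n_traits"] == 1).all()

    def test_identical_sets_brute_force(self):
        cpgs = {f"c{i}" for i in range(5)}
        out = metaconsist.multi_trait_overlap({f"O{j}": cpgs for j in range(5)})
        assert (out["per_cpg"]["n_traits"] == 5).all()
        assert out["at_least"].set_index("k")["count"][5] == 5


class TestRegionFilter:
    def _ann(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "cpg_id": [f"c{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
                "gene": "", "island_relation": "", "gene_context": "",
            }
        )

    def test_single_merge_of_four(self):
        ann = self._ann([100, 300, 600, 900])
        regions = metaconsist.region_filter([f"c{i}" for i in range(4)], ann)
        assert len(regions) == 1
        assert regions.iloc[0][["start", "end", "n_cpgs"]].tolist() == [100, 900, 4]

    def test_three_clustered_dropped(self):
        ann = self._ann([100, 300, 600])
        regions = metaconsist.region_filter(["c0", "c1", "c2"], ann)
        assert len(regions) == 0

    def test_gap_splits_runs(self):
        ann = self._ann([100, 300, 6000, 6200, 6400, 6600])
        regions = metaconsist.region_filter([f"c{i}" for i in range(6)], ann, max_gap_bp=1000)
        assert len(regions) == 1
        assert regions.iloc[0]["n_cpgs"] == 4
        assert regions.iloc[0]["start"] == 6000

    def test_chromosomes_never_merge(self):
        ann = pd.concat(
            [self._ann([100, 200], "chr1"), self._ann([300, 400], "chr2").assign(cpg_id=["c2", "c3"])]
        )
        regions = metaconsist.region_filter(["c0", "c1", "c2", "c3"], ann, min_cpgs=2)
        assert len(regions) == 2

    def test_unannotated_hit_raises(self):
        ann = self._ann([100])
        with pytest.raises(ValueError, match="missing from annotation"):
            metaconsist.region_filter(["c0", "cZZ"], ann)
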