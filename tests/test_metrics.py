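"""Richness, reaction abundance, reactobiome, iRSE and group testing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microgem as mg
from microgem.metrics import CPF_SCALE, sample_presence


@pytest.fixture
def toy_pool():
    return mg.build_reaction_pool({"m1": ["r1", "r2"], "m2": ["r2", "r3"]})


def ab_table(values, msps=("m1", "m2"), samples=("s1",)):
    return pd.DataFrame(np.asarray(values, dtype=float), index=list(msps),
                        columns=list(samples))


class TestPool:
    def test_union_and_membership(self, toy_pool):
        assert toy_pool.reactions == ["r1", "r2", "r3"]
        assert toy_pool.membership["m1"].sum() == 2
        assert toy_pool.membership.loc["r3", "m1"] == 0

    def test_membership_column_sums_equal_model_sizes(self, toy_pool):
        assert toy_pool.membership.sum().to_dict() == {"m1": 2, "m2": 2}

    def test_single_model_pool(self):
        pool = mg.build_reaction_pool({"m": ["a", "b"]})
        assert pool.reactions == ["a", "b"]

    def test_duplicate_model_ids_rejected(self, demo, species_gems):
        _, tuned = species_gems
        with pytest.raises(ValueError, match="duplicate"):
            mg.build_reaction_pool([tuned[0], tuned[0]])


class TestRichness:
    def test_union_count(self, toy_pool):
        assert mg.reaction_richness(toy_pool, ab_table([[0.7], [0.3]]))["s1"] == 3

    def test_all_zero_abundance(self, toy_pool):
        assert mg.reaction_richness(toy_pool, ab_table([[0.0], [0.0]]))["s1"] == 0

    def test_monotone_no_double_count(self):
        pool = mg.build_reaction_pool({"m1": ["r1", "r2"], "m2": ["r2", "r3"], "m3": ["r1"]})
        two = mg.reaction_richness(pool, ab_table([[0.7], [0.3], [0.0]], msps=("m1", "m2", "m3")))
        three = mg.reaction_richness(pool, ab_table([[0.7], [0.3], [0.1]], msps=("m1", "m2", "m3")))
        assert two["s1"] == three["s1"] == 3

    def test_rescaling_invariance(self, toy_pool):
        a = mg.reaction_richness(toy_pool, ab_table([[0.7], [0.3]]))
        b = mg.reaction_richness(toy_pool, ab_table([[7.0], [3.0]]))
        assert a.equals(b)


class TestReactionAbundance:
    def test_hand_arithmetic(self, toy_pool):
        # a=(0.7, 0.3); r2 in both, r1 only in m1, r3 only in m2:
        # raw = (0.7, 1.0, 0.3), relative = raw / 2
        rel = mg.reaction_abundance(toy_pool, ab_table([[0.7], [0.3]]))
        assert rel["s1"].tolist() == pytest.approx([0.35, 0.5, 0.15])
        assert rel["s1"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_msp_uniform(self):
        pool = mg.build_reaction_pool({"m": ["a", "b", "c"]})
        rel = mg.reaction_abundance(pool, ab_table([[0.4]], msps=("m",)))
        assert rel["s1"].tolist() == pytest.approx([1 / 3] * 3)

    def test_undetected_reaction_zero(self, toy_pool):
        rel = mg.reaction_abundance(toy_pool, ab_table([[1.0], [0.0]]))
        assert rel.loc["r3", "s1"] == 0.0

    def test_empty_sample_flagged(self, toy_pool):
        with pytest.warns(UserWarning, match="no detected MSP"):
            rel = mg.reaction_abundance(toy_pool, ab_table([[0.0], [0.0]]))
        assert (rel["s1"] == 0).all()


class TestReactobiome:
    def test_expectation_formula(self, toy_pool):
        cpf = mg.reactobiome(toy_pool, ab_table([[0.7], [0.3]]))
        assert cpf.loc["r2", "s1"] == pytest.approx(500.0)
        assert cpf.loc["r1", "s1"] == pytest.approx(350.0)
        assert cpf.loc["r3", "s1"] == pytest.approx(150.0)

    def test_scale_invariance(self, toy_pool):
        a = mg.reactobiome(toy_pool, ab_table([[0.7], [0.3]]))
        b = mg.reactobiome(toy_pool, ab_table([[0.35], [0.15]]))
        pd.testing.assert_frame_equal(a, b)

    def test_all_carrier_bound_attained(self):
        pool = mg.build_reaction_pool({"m1": ["r"], "m2": ["r"]})
        cpf = mg.reactobiome(pool, ab_table([[0.2], [0.5]]))
        assert cpf.loc["r", "s1"] == pytest.approx(CPF_SCALE)

    def test_conservation_identity(self, demo, pool_and_cpf):
        """sum_r CPF(r,s) = 500 x abundance-weighted mean reactome size."""
        pool, cpf = pool_and_cpf
        ab = demo.abundance
        sizes = pool.membership.sum(axis=0)  # reactions per model
        for s in ab.columns[:10]:
            w = ab[s] / ab[s].sum()
            expected = CPF_SCALE * float((w * sizes.loc[ab.index]).sum())
            assert cpf[s].sum() == pytest.approx(expected, rel=1e-9)


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper-tail enumeration with integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestIRSE:
    def test_worked_example(self):
        presence = pd.Series([1] * 5 + [0] * 5, index=[f"r{i}" for i in range(10)])
        pathways = {"path": {"r0", "r1", "r2", "r3"}}  # K=4, n=5, k=4
        res = mg.irse(presence, pathways)
        assert res.loc["path", "p_value"] == pytest.approx(6 / 252)

    def test_zero_overlap_p_one(self):
        presence = pd.Series([0, 0, 1, 1], index=list("abcd"))
        res = mg.irse(presence, {"p": {"a", "b"}})
        assert res.loc["p", "p_value"] == pytest.approx(1.0)

    def test_saturated_sample_p_one(self):
        presence = pd.Series([1] * 6, index=list("abcdef"))
        res = mg.irse(presence, {"p1": {"a", "b"}, "p2": {"c"}})
        assert res["p_value"].tolist() == pytest.approx([1.0, 1.0])

    def test_empty_pathway_skipped_and_reported(self):
        presence = pd.Series([1, 0], index=list("ab"))
        res = mg.irse(presence, {"good": {"a"}, "outside": {"zz"}})
        assert "outside" not in res.index
        assert res.attrs["skipped_pathways"] == ["outside"]

    def test_matches_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(4, 26))
            ids = [f"r{i}" for i in range(N)]
            presence = pd.Series(rng.integers(0, 2, N), index=ids)
            K = int(rng.integers(1, N + 1))
            members = set(rng.choice(ids, size=K, replace=False))
            res = mg.irse(presence, {"p": members})
            n = int(presence.sum())
            k = len(members & {i for i, v in presence.items() if v})
            assert res.loc["p", "p_value"] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), rel=1e-12
            )

    def test_q_values_bh_adjusted(self):
        presence = pd.Series([1] * 3 + [0] * 17, index=[f"r{i}" for i in range(20)])
        res = mg.irse(presence, {"a": {"r0", "r1", "r2"}, "b": {"r10", "r11"}})
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()


class TestDifferential:
    def _groups(self, n_case, n_ctrl):
        samples = [f"c{i}" for i in range(n_ctrl)] + [f"x{i}" for i in range(n_case)]
        return samples, pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=samples)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        samples, groups = self._groups(10, 10)
        cpf = pd.DataFrame(rng.uniform(0, 500, size=(30, 20)),
                           index=[f"r{i}" for i in range(30)], columns=samples)
        res = mg.differential_reactions(cpf, groups)
        # permuting labels of iid data: expect no q below 0.05
        assert (res["q_value"] >= 0.05).all()

    def test_planted_shift_recovered_with_minimal_q(self):
        rng = np.random.default_rng(2)
        samples, groups = self._groups(20, 20)
        cpf = pd.DataFrame(rng.normal(250, 10, size=(25, 40)),
                           index=[f"r{i}" for i in range(25)], columns=samples)
        cpf.loc["r0", groups == "case"] += 200.0
        res = mg.differential_reactions(cpf, groups)
        assert res.loc["r0", "q_value"] == res["q_value"].min()
        assert res.loc["r0", "q_value"] < 0.05
        assert res.loc["r0", "direction"] == 1.0

    def test_bh_stepup_values(self):
        assert stats.false_discovery_control(
            [0.001, 0.02, 0.9], method="bh"
        ) == pytest.approx([0.003, 0.03, 0.9])

    def test_constant_reaction_flagged_p_one(self):
        samples, groups = self._groups(3, 3)
        cpf = pd.DataFrame(
            [[500.0] * 6, [1, 2, 3, 4, 5, 6]], index=["const", "varies"], columns=samples
        )
        res = mg.differential_reactions(cpf, groups)
        assert res.loc["const", "constant"]
        assert res.loc["const", "p_value"] == 1.0

    def test_paired_mode_runs(self):
        rng = np.random.default_rng(3)
        samples, groups = self._groups(8, 8)
        cpf = pd.DataFrame(rng.normal(100, 5, size=(10, 16)),
                           index=[f"r{i}" for i in range(10)], columns=samples)
        res = mg.differential_reactions(cpf, groups, paired=True)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()

    def test_too_few_samples_rejected(self):
        samples, groups = self._groups(1, 3)
        cpf = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=samples)
        with pytest.raises(ValueError, match="at least 2"):
            mg.differential_reactions(cpf, groups)


class TestPresence:
    def test_presence_matches_richness(self, demo, pool_and_cpf):
        pool, _ = pool_and_cpf
        pres = sample_presence(pool, demo.abundance)
        rich = mg.reaction_richness(pool, demo.abundance)
        assert (pres.sum(axis=0) == rich).all()
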