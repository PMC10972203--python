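"""Reaction states, taxonomy frequencies, scores and thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microgem as mg
from microgem.scoring import combined_frequency
from microgem.tables import TAXONOMY_LEVELS

from conftest import make_toy_reference


def brute_force_frequencies(states: pd.DataFrame, tax: pd.DataFrame) -> dict:
    """Independent oracle: explicit group-by-and-average per level."""
    out = {}
    for level in TAXONOMY_LEVELS:
        mat = pd.DataFrame(0.0, index=states.index, columns=states.columns)
        for msp in states.columns:
            taxon = tax.loc[msp, level]
            if str(taxon).lower() == "unclassified":
                members = [msp]
            else:
                members = [m for m in states.columns if tax.loc[m, level] == taxon]
            for rxn in states.index:
                vals = [states.loc[rxn, m] for m in members]
                mat.loc[rxn, msp] = sum(vals) / len(vals)
        out[level] = mat
    return out


def random_fixture(rng, n_rxns, n_msps, with_unclassified=True):
    states = pd.DataFrame(
        rng.integers(0, 2, size=(n_rxns, n_msps)).astype(np.int8),
        index=[f"r{i}" for i in range(n_rxns)],
        columns=[f"m{j}" for j in range(n_msps)],
    )
    tax = pd.DataFrame(index=pd.Index(states.columns, name="msp_id"))
    tax["species"] = [f"sp{j}" for j in range(n_msps)]
    for level in TAXONOMY_LEVELS:
        n_taxa = max(1, int(rng.integers(1, n_msps + 1)))
        labels = [f"{level[:3]}{rng.integers(n_taxa)}" for _ in range(n_msps)]
        if with_unclassified:
            labels = [
                "unclassified" if rng.random() < 0.15 else lab for lab in labels
            ]
        tax[level] = labels
    return states, tax


class TestStates:
    def test_or_rule_either_mode(self):
        gem, msps, _ = make_toy_reference()
        gem.reaction("R_PA").gpr_rule = "gA or gB1"
        for mode in ("boolean", "any_gene"):
            states = mg.msp_reaction_states(gem, msps, mode=mode)
            assert states.loc["R_PA", "msp1"] == 1

    def test_and_rule_distinguishes_modes(self):
        gem, msps, _ = make_toy_reference()
        gem.reaction("R_PA").gpr_rule = "gA and gB1"
        assert mg.msp_reaction_states(gem, msps, mode="boolean").loc["R_PA", "msp1"] == 0
        assert mg.msp_reaction_states(gem, msps, mode="any_gene").loc["R_PA", "msp1"] == 1

    def test_empty_msp_all_zero_and_empty_gpr_zero(self):
        gem, msps, _ = make_toy_reference()
        msps = dict(msps, empty=set())
        states = mg.msp_reaction_states(gem, msps)
        assert states["empty"].sum() == 0
        assert (states.loc["EX_A"] == 0).all()  # no GPR -> absent everywhere

    def test_gene_outside_catalog_rejected(self):
        gem, msps, _ = make_toy_reference()
        msps = dict(msps, rogue={"not_a_gene"})
        with pytest.raises(ValueError, match="outside the catalogue"):
            mg.msp_reaction_states(gem, msps, catalog_genes={"gT", "gA", "gB1", "gB2"})


class TestFrequencies:
    def test_hand_computed_group_means(self):
        states = pd.DataFrame(
            {"m1": [1], "m2": [1], "m3": [0], "m4": [0]}, index=["r"]
        ).astype(np.int8)
        tax = pd.DataFrame(
            {
                "species": list("abcd"),
                "genus": ["g1", "g1", "g1", "g2"],
                "family": ["f1"] * 4,
                "order": ["o1"] * 4,
                "class": ["c1"] * 4,
                "phylum": ["p1"] * 4,
            },
            index=pd.Index(["m1", "m2", "m3", "m4"], name="msp_id"),
        )
        freqs = mg.taxon_reaction_frequencies(states, tax)
        assert freqs["genus"].loc["r"].tolist() == [2 / 3, 2 / 3, 2 / 3, 0.0]
        assert freqs["phylum"].loc["r"].tolist() == [0.5] * 4  # 2 of 4 carriers
        # singleton genus: frequency equals own state
        assert freqs["genus"].loc["r", "m4"] == 0.0

    def test_unclassified_never_pools(self):
        states = pd.DataFrame({"m1": [1], "m2": [0]}, index=["r"]).astype(np.int8)
        tax = pd.DataFrame(
            {"species": ["a", "b"], "genus": ["unclassified"] * 2,
             "family": ["f"] * 2, "order": ["o"] * 2, "class": ["c"] * 2,
             "phylum": ["p"] * 2},
            index=pd.Index(["m1", "m2"], name="msp_id"),
        )
        freqs = mg.taxon_reaction_frequencies(states, tax)
        assert freqs["genus"].loc["r", "m1"] == 1.0  # own state, not 0.5
        assert freqs["genus"].loc["r", "m2"] == 0.0
        assert freqs["family"].loc["r"].tolist() == [0.5, 0.5]

    def test_missing_taxonomy_record_rejected(self):
        states = pd.DataFrame({"mX": [1]}, index=["r"]).astype(np.int8)
        tax = pd.DataFrame(
            {"species": ["a"], "genus": ["g"], "family": ["f"], "order": ["o"],
             "class": ["c"], "phylum": ["p"]}, index=pd.Index(["other"], name="msp_id")
        )
        with pytest.raises(ValueError, match="without taxonomy"):
            mg.taxon_reaction_frequencies(states, tax)


class TestScores:
    def _fixture(self, state, level_freqs):
        states = pd.DataFrame({"m": [state]}, index=["r"]).astype(np.int8)
        freqs = {
            level: pd.DataFrame({"m": [f]}, index=["r"])
            for level, f in zip(TAXONOMY_LEVELS, level_freqs)
        }
        return states, freqs

    def test_mean_over_levels_arithmetic(self):
        states, freqs = self._fixture(1, (0.6, 0.5, 0.4, 0.3, 0.2))
        assert mg.reaction_scores(states, freqs).loc["r", "m"] == pytest.approx(1.4)

    def test_single_level_mode(self):
        states, freqs = self._fixture(1, (0.6, 0.5, 0.4, 0.3, 0.2))
        assert mg.reaction_scores(states, freqs, freq_mode="genus").loc["r", "m"] == pytest.approx(1.6)

    def test_zero_and_maximum_bounds(self):
        states, freqs = self._fixture(0, (0.0,) * 5)
        assert mg.reaction_scores(states, freqs).loc["r", "m"] == 0.0
        states, freqs = self._fixture(1, (1.0,) * 5)
        assert mg.reaction_scores(states, freqs).loc["r", "m"] == 2.0


class TestThresholds:
    def test_min_of_positive_frequencies(self):
        freqs = {"genus": pd.DataFrame([[0.2, 0.5], [1.0, 0.0]])}
        assert mg.taxonomy_thresholds(freqs) == {"genus": 0.2}

    def test_single_positive_value(self):
        freqs = {"genus": pd.DataFrame([[0.0, 0.7]])}
        assert mg.taxonomy_thresholds(freqs)["genus"] == pytest.approx(0.7)

    def test_all_zero_level_errors(self):
        with pytest.raises(ValueError, match="threshold undefined"):
            mg.taxonomy_thresholds({"genus": pd.DataFrame([[0.0, 0.0]])})


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_frequencies_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        states, tax = random_fixture(rng, int(rng.integers(1, 12)), int(rng.integers(1, 8)))
        freqs = mg.taxon_reaction_frequencies(states, tax)
        oracle = brute_force_frequencies(states, tax)
        for level in TAXONOMY_LEVELS:
            np.testing.assert_allclose(
                freqs[level].values, oracle[level].values, atol=1e-12
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_column_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        states, tax = random_fixture(rng, 10, 6)
        perm = rng.permutation(states.columns)
        freqs = mg.taxon_reaction_frequencies(states, tax)
        freqs_p = mg.taxon_reaction_frequencies(states[perm], tax)
        for level in TAXONOMY_LEVELS:
            pd.testing.assert_frame_equal(freqs[level][perm], freqs_p[level])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_score_bounds_and_dominance(self, seed):
        rng = np.random.default_rng(seed)
        states, tax = random_fixture(rng, 12, 6)
        freqs = mg.taxon_reaction_frequencies(states, tax)
        scores = mg.reaction_scores(states, freqs)
        assert (scores.values >= 0).all() and (scores.values <= 2).all()
        assert (scores.values >= states.values - 1e-12).all()
        f = combined_frequency(freqs)
        zero = scores.values == 0
        assert ((states.values == 0) & (f.values == 0))[zero].all()

    def test_uniform_taxon_frequency_equals_state(self):
        # all MSPs in a taxon share a state -> frequency equals that state
        rng = np.random.default_rng(7)
        states, tax = random_fixture(rng, 8, 6, with_unclassified=False)
        tax["genus"] = "only_genus"
        states.iloc[0, :] = 1
        states.iloc[1, :] = 0
        freqs = mg.taxon_reaction_frequencies(states, tax)
        assert (freqs["genus"].iloc[0] == 1.0).all()
        assert (freqs["genus"].iloc[1] == 0.0).all()
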