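import numpy as np
import pandas as pd
import pytest

from coda_age import (
    EffectTable,
    RhoGraph,
    bin_by_taxon,
    dirichlet_instances,
    effect_size,
    pairwise_effects,
    select_explanatory,
)
from coda_age.differential import successive_pairs
from coda_age.synthetic_data import SyntheticSpec, generate_table
from coda_age.table_io import parse_lineage


@pytest.fixture(scope="module")
def mc_and_labels():
    table, _ = generate_table(
        SyntheticSpec(n_groups=3, samples_per_group=10, n_otus=15, seed=5)
    )
    mc = dirichlet_instances(table, K=8, seed=5)
    return mc, table.groups()


class TestEffectSize:
    def test_antisymmetry(self, mc_and_labels):
        mc, labels = mc_and_labels
        ab = effect_size(mc, labels, ("g1", "g2"), seed=3)
        ba = effect_size(mc, labels, ("g2", "g1"), seed=3)
        np.testing.assert_allclose(ab["effect"], -ba["effect"], atol=1e-12)
        np.testing.assert_allclose(ab["diff_btw"], -ba["diff_btw"], atol=1e-12)
        np.testing.assert_allclose(ab["diff_win"], ba["diff_win"], atol=1e-12)

    def test_diff_win_nonnegative_finite(self, mc_and_labels):
        mc, labels = mc_and_labels
        out = effect_size(mc, labels, ("g1", "g3"), seed=0)
        assert (out["diff_win"] >= 0).all()
        assert np.isfinite(out[["diff_btw", "diff_win", "effect"]]).all().all()

    def test_unknown_label(self, mc_and_labels):
        mc, labels = mc_and_labels
        with pytest.raises(ValueError, match="unknown group"):
            effect_size(mc, labels, ("g1", "nope"))

    def test_small_group_errors(self, mc_and_labels):
        mc, labels = mc_and_labels
        tweaked = labels.copy()
        tweaked.iloc[:9] = "g2"  # leaves one g1 sample
        with pytest.raises(ValueError, match="need >= 2"):
            effect_size(mc, tweaked, ("g1", "g2"))

    def test_deterministic_given_seed(self, mc_and_labels):
        mc, labels = mc_and_labels
        a = effect_size(mc, labels, ("g1", "g2"), seed=7)
        b = effect_size(mc, labels, ("g1", "g2"), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_spiked_otu_detected(self):
        table, truth = generate_table(
            SyntheticSpec(
                n_groups=2, samples_per_group=50, n_otus=100,
                group_shifts={(1, 0): 3.0},  # 8-fold change
                depth_mean=1e4, seed=21,
            )
        )
        mc = dirichlet_instances(table, K=16, seed=21)
        eff = effect_size(mc, table.groups(), ("g1", "g2"), seed=21)
        assert eff.set_index("otu_id").loc["OTU0000", "effect"] >= 1.0

    def test_more_instances_reduce_seed_variance(self):
        table, _ = generate_table(
            SyntheticSpec(n_groups=2, samples_per_group=10, n_otus=12, seed=2)
        )
        labels = table.groups()

        def seed_sd(K):
            effs = []
            for s in range(10):
                mc = dirichlet_instances(table, K=K, seed=100 + s)
                e = effect_size(mc, labels, ("g1", "g2"), seed=s)
                effs.append(e["effect"].to_numpy())
            return np.std(np.stack(effs), axis=0).mean()

        assert seed_sd(128) < seed_sd(16)


class TestPairwiseEffects:
    def test_all_pairs_combinatorics(self, mc_and_labels):
        mc, labels = mc_and_labels
        eff = pairwise_effects(mc, labels, pairs="all", seed=0)
        assert len(eff.pairs) == 3

    def test_successive_seven_cohorts(self):
        order = ["3-6", "8-12", "13-14", "19-24", "30-50", "60-79", ">94"]
        assert len(successive_pairs(order)) == 6

    def test_successive_pairs_follow_declared_order(self, mc_and_labels):
        mc, labels = mc_and_labels
        eff = pairwise_effects(
            mc, labels, pairs="successive", cohort_order=["g3", "g1", "g2"], seed=0
        )
        assert eff.pairs == [("g3", "g1"), ("g1", "g2")]

    def test_unknown_cohort_in_order(self, mc_and_labels):
        mc, labels = mc_and_labels
        with pytest.raises(ValueError, match="unknown"):
            pairwise_effects(mc, labels, cohort_order=["g1", "g2", "gX"])

    def test_explicit_pair_list(self, mc_and_labels):
        mc, labels = mc_and_labels
        eff = pairwise_effects(mc, labels, pairs=[("g2", "g3")], seed=0)
        assert eff.pairs == [("g2", "g3")]


def _toy_effect_table(effects: dict[str, float]) -> EffectTable:
    rows = [
        {"otu_id": o, "group_a": "A", "group_b": "B",
         "diff_btw": v, "diff_win": 1.0, "effect": v}
        for o, v in effects.items()
    ]
    return EffectTable(pd.DataFrame(rows))


def _toy_rho(otus, links=()) -> RhoGraph:
    mat = pd.DataFrame(np.zeros((len(otus), len(otus))), index=otus, columns=otus)
    np.fill_diagonal(mat.values, 1.0)
    for i, j, v in links:
        mat.loc[i, j] = mat.loc[j, i] = v
    return RhoGraph(mat)


class TestSelectExplanatory:
    def test_effect_only(self):
        eff = _toy_effect_table({"a": 1.2, "b": 0.3})
        sel = select_explanatory(eff, _toy_rho(["a", "b"]))
        assert sel.frame.to_dict("records") == [{"otu_id": "a", "reason": "effect"}]

    def test_below_both_cuts_dropped(self):
        eff = _toy_effect_table({"a": 0.5, "b": -0.9})
        sel = select_explanatory(eff, _toy_rho(["a", "b"]))
        assert sel.otu_ids == []

    def test_rho_and_both_reasons(self):
        eff = _toy_effect_table({"a": 1.5, "b": 0.1, "c": 0.0})
        rho = _toy_rho(["a", "b", "c"], links=[("a", "b", 0.8)])
        sel = select_explanatory(eff, rho)
        reasons = dict(zip(sel.frame["otu_id"], sel.frame["reason"]))
        assert reasons == {"a": "both", "b": "rho"}

    def test_negative_effect_counts(self):
        eff = _toy_effect_table({"a": -1.2, "b": 0.0})
        sel = select_explanatory(eff, _toy_rho(["a", "b"]))
        assert sel.otu_ids == ["a"]

    def test_mismatched_otu_sets(self):
        eff = _toy_effect_table({"a": 1.2, "b": 0.3})
        with pytest.raises(ValueError, match="different OTU sets"):
            select_explanatory(eff, _toy_rho(["a", "b", "c"]))

    def test_recovery_on_planted_fixture(self):
        from coda_age.association import expected_rho
        from coda_age.synthetic_data import make_fixture

        table, truth = make_fixture("spiked_blocks")
        mc = dirichlet_instances(table, K=16, seed=11)
        eff = pairwise_effects(mc, table.groups(), pairs="all", seed=11)
        rho = expected_rho(mc)
        sel = select_explanatory(eff, rho)
        true, got = set(truth.true_otus), set(sel.otu_ids)
        assert len(true & got) >= 14
        assert len(got - true) <= 2


class TestBinByTaxon:
    def _tax(self):
        return parse_lineage(
            {
                "a": "Bacteria;F;C;O;Fa;Blautia",
                "b": "Bacteria;F;C;O;Fa;Blautia",
                "c": "Bacteria;F;C;O;Fa;Dorea",
                "d": "",
            }
        )

    def test_single_genus_single_bin(self):
        eff = _toy_effect_table({"a": 1.0, "b": 2.0})
        binned, summary = bin_by_taxon(eff, self._tax(), rank="genus")
        assert set(binned["taxon"]) == {"Blautia"}
        assert len(summary) == 1

    def test_unclassified_pooled(self):
        eff = _toy_effect_table({"a": 1.0, "c": 0.5, "d": 0.2})
        binned, _ = bin_by_taxon(eff, self._tax(), rank="genus")
        assert binned.set_index("otu_id").loc["d", "taxon"] == "unclassified"

    def test_per_bin_medians_group_by_oracle(self):
        eff = _toy_effect_table({"a": 1.0, "b": 3.0, "c": 0.5, "d": -2.0})
        _, summary = bin_by_taxon(eff, self._tax(), rank="genus")
        med = summary.set_index("taxon")["median_effect"]
        assert med["Blautia"] == pytest.approx(np.median([1.0, 3.0]))
        assert med["Dorea"] == pytest.approx(0.5)
        n_above = summary.set_index("taxon")["n_above_cut"]
        assert n_above["unclassified"] == 1  # |-2| >= 1

    def test_unknown_rank(self):
        eff = _toy_effect_table({"a": 1.0})
        with pytest.raises(ValueError, match="rank"):
            bin_by_taxon(eff, self._tax(), rank="species")

    def test_long_format_for_successive_layout(self, mc_and_labels):
        mc, labels = mc_and_labels
        eff = pairwise_effects(mc, labels, pairs="successive",
                               cohort_order=["g1", "g2", "g3"], seed=0)
        tax = parse_lineage({o: "Bacteria;F;C;O;Fa;G1" for o in mc.otu_ids})
        binned, summary = bin_by_taxon(eff, tax)
        assert set(binned.columns) >= {"otu_id", "group_a", "group_b", "effect", "taxon"}
        assert len(binned) == 2 * mc.n_otus
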