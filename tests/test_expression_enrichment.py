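"""Enrichment filter, secretome partition, bin profiles, cluster summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moltmap.errors import InputError
from moltmap.expression_enrichment import (
    bin_abundance_profile,
    classify_tissue_enriched,
    cluster_summary,
    lagged_bin_test,
    network_density,
    partition_secretome,
    summarize_secretome_strata,
)


class TestClassifyTissueEnriched:
    def test_clear_enrichment_passes(self):
        mat = pd.DataFrame(
            {"pharynx": [40.0, 24.0], "gut": [10.0, 1.0], "glia": [8.0, 1.0]},
            index=["hit", "too_low"],
        )
        assert classify_tissue_enriched(mat, "pharynx") == {"hit"}

    def test_matches_brute_force_enumeration(self, rng):
        genes = [f"g{i}" for i in range(60)]
        mat = pd.DataFrame(
            rng.uniform(0, 60, size=(60, 5)),
            index=genes, columns=list("ABCDE"),
        )
        for mode in ("max", "mean"):
            got = classify_tissue_enriched(mat, "C", fold=1.5, min_tpm=25, mode=mode)
            expected = set()
            for g in genes:
                row = mat.loc[g]
                others = row.drop("C")
                ref = others.max() if mode == "max" else others.mean()
                if row["C"] > 1.5 * ref and row["C"] >= 25:
                    expected.add(g)
            assert got == expected

    def test_single_tissue_matrix_is_an_input_error(self):
        with pytest.raises(InputError):
            classify_tissue_enriched(pd.DataFrame({"pharynx": [1.0]}), "pharynx")

    def test_unknown_tissue_is_an_input_error(self):
        mat = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(InputError):
            classify_tissue_enriched(mat, "zzz")

    def test_noise_free_synthetic_recovery_is_exact(self, clean_data):
        truth = clean_data.truth.set_index("gene_id")
        planted = set(truth.index[truth["enriched_tissue"] == "pharynx"])
        got = classify_tissue_enriched(clean_data.tissue_matrix, "pharynx")
        assert got == planted


class TestPartitionSecretome:
    def test_cutoff_is_inclusive(self):
        sec, non = partition_secretome(
            ["a", "b"], {"a": 0.45, "b": 0.449}
        )
        assert sec == {"a"} and non == {"b"}

    def test_sets_partition_the_input(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = {g: rng.random() for g in genes}
        sec, non = partition_secretome(genes, scores)
        assert sec | non == set(genes)
        assert sec & non == set()

    def test_missing_score_goes_non_secreted_with_warning(self, caplog):
        sec, non = partition_secretome(["a", "b"], {"a": 0.9})
        assert sec == {"a"} and non == {"b"}
        assert any("without a score" in r.message for r in caplog.records)

    def test_exact_agreement_with_planted_flags(self, small_data):
        truth = small_data.truth.set_index("gene_id")
        scores = small_data.signalp_scores.set_index("gene_id")["signalp_score"]
        sec, _ = partition_secretome(list(truth.index), scores)
        assert sec == set(truth.index[truth["secreted"]])


class TestBinAbundanceProfile:
    def test_identical_values_give_p_one(self):
        genes = [f"g{i}" for i in range(8)]
        prof = bin_abundance_profile(
            genes,
            {g: 7.0 for g in genes},
            {g: i + 1 for i, g in enumerate(genes)},
        )
        assert np.allclose(prof.table["p"], 1.0)
        assert np.allclose(prof.table["mean"].dropna(), 7.0)

    def test_closed_form_one_sample_t(self):
        """(10,20,30) vs mean 10: t = sqrt(3), p(df=2) ~ 0.2254."""
        prof = bin_abundance_profile(
            ["a", "b", "c"],
            {"a": 10.0, "b": 20.0, "c": 30.0},
            {"a": 2, "b": 2, "c": 2},
            global_mean=10.0,
        )
        row = prof.table.set_index("bin").loc[2]
        assert row["mean"] == pytest.approx(20.0)
        expected_p = 2 * stats.t.sf(np.sqrt(3), df=2)
        assert row["p"] == pytest.approx(expected_p, abs=1e-6)
        assert row["p"] == pytest.approx(0.2254, abs=1e-3)

    def test_weighted_mean_of_bins_equals_global_mean(self, rng):
        genes = [f"g{i}" for i in range(100)]
        expr = {g: float(rng.uniform(1, 100)) for g in genes}
        hours = {g: int(rng.integers(1, 9)) for g in genes}
        prof = bin_abundance_profile(genes, expr, hours)
        t = prof.table.dropna(subset=["mean"])
        pooled = (t["mean"] * t["n"]).sum() / t["n"].sum()
        assert pooled == pytest.approx(prof.global_mean, rel=1e-9)
        assert prof.table["n"].sum() == len(genes)

    def test_empty_bin_warns_and_gets_p_one(self, caplog):
        prof = bin_abundance_profile(["a"], {"a": 5.0}, {"a": 3})
        row = prof.table.set_index("bin").loc[1]
        assert np.isnan(row["mean"]) and row["p"] == 1.0
        assert any("empty" in r.message for r in caplog.records)


class TestClusterSummary:
    mat = pd.DataFrame(
        {"c1": [2.0, 5.0], "c2": [4.0, 9.0], "c3": [1.0, 2.0]},
        index=["g1", "g2"],
    )

    def test_single_cluster_type_is_identity(self):
        out = cluster_summary(self.mat, {"pm": ["c2"]}, mode="average")
        assert (out["pm"] == self.mat["c2"]).all()
        out_max = cluster_summary(self.mat, {"pm": ["c2"]}, mode="max-average")
        assert (out_max["pm"] == self.mat["c2"]).all()

    def test_average_mode(self):
        out = cluster_summary(self.mat, {"pm": ["c1", "c2"]}, mode="average")
        assert out.loc["g1", "pm"] == pytest.approx(3.0)

    def test_max_average_picks_one_cluster_for_the_whole_type(self):
        # gene-set averages: c1=3.5, c2=6.5, c3=1.5 -> c2 wins for every gene
        out = cluster_summary(
            self.mat, {"pm": ["c1", "c2", "c3"]}, mode="max-average"
        )
        assert (out["pm"] == self.mat["c2"]).all()

    def test_average_is_permutation_invariant(self):
        a = cluster_summary(self.mat, {"pm": ["c1", "c2", "c3"]}, mode="average")
        b = cluster_summary(self.mat, {"pm": ["c3", "c1", "c2"]}, mode="average")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_cluster_is_an_input_error(self):
        with pytest.raises(InputError):
            cluster_summary(self.mat, {"pm": ["c9"]})


class TestLaggedBinTest:
    def test_identical_bins_are_never_flagged(self):
        vals = {b: np.array([5.0, 5.0, 5.0]) for b in range(1, 9)}
        assert not any(lagged_bin_test(vals).values())

    def test_strong_step_is_flagged(self, rng):
        vals = {b: rng.normal(10, 1, 20) for b in range(1, 9)}
        vals[6] = rng.normal(100, 1, 20)
        flags = lagged_bin_test(vals)
        assert flags[6]
        assert not flags[5]

    def test_first_two_bins_have_no_comparator(self, rng):
        vals = {b: rng.normal(10, 1, 20) for b in range(1, 9)}
        vals[1] = rng.normal(1000, 1, 20)
        vals[2] = rng.normal(1000, 1, 20)
        flags = lagged_bin_test(vals)
        assert not flags[1] and not flags[2]

    def test_tiny_bins_are_never_flagged(self, caplog):
        vals = {4: np.array([1.0]), 6: np.array([100.0, 101.0])}
        assert not lagged_bin_test(vals)[6]


class TestNetworkDensity:
    def test_published_style_ratio(self, rng):
        nodes = [f"p{i}" for i in range(20)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        idx = rng.choice(len(pairs), size=36, replace=False)
        density, n_edges, n_nodes = network_density(nodes, [pairs[i] for i in idx])
        assert (density, n_edges, n_nodes) == (1.8, 36, 20)

    def test_no_edges_is_zero(self):
        assert network_density(["a", "b"], [])[0] == 0.0

    def test_complete_graph_on_four_nodes(self):
        nodes = list("abcd")
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        assert network_density(nodes, edges)[0] == pytest.approx(1.5)

    def test_foreign_edges_dropped_with_warning(self, caplog):
        density, n_edges, _ = network_density(["a", "b"], [("a", "b"), ("a", "z")])
        assert n_edges == 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_empty_node_set_is_an_input_error(self):
        with pytest.raises(InputError):
            network_density([], [])


class TestSecretomeStrata:
    def test_fractions_and_counts(self):
        scores = {"a": 0.9, "b": 0.1, "c": 0.5, "d": 0.2, "e": 0.8, "f": 0.1}
        out = summarize_secretome_strata({"a", "b"}, {"c", "d"}, {"e", "f"}, scores)
        assert out["n"].sum() == 6
        by = out.set_index("stratum")
        assert by.loc["oscillating_enriched", "fraction"] == pytest.approx(0.5)
        assert by.loc["non_oscillating", "n_secreted"] == 1

    def test_overlapping_strata_is_an_input_error(self):
        with pytest.raises(InputError):
            summarize_secretome_strata({"a"}, {"a"}, {"b"}, {"a": 1, "b": 0})

    def test_empty_stratum_is_an_input_error(self):
        with pytest.raises(InputError):
            summarize_secretome_strata({"a"}, set(), {"b"}, {"a": 1, "b": 0})
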