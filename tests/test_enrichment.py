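import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirspot import enrichment, reference_data
from mirspot.errors import ConsistencyError


def exact_binomial_upper(k, n, p):
    """Oracle: exhaustive expansion of the binomial upper tail."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def exact_hypergeom_upper(overlap, n_univ, n_set, n_sample):
    """Oracle: enumerate the hypergeometric upper tail with exact fractions."""
    total = math.comb(n_univ, n_sample)
    hits = sum(
        math.comb(n_set, i) * math.comb(n_univ - n_set, n_sample - i)
        for i in range(overlap, min(n_set, n_sample) + 1))
    return hits / total


class TestTargetFilter:
    @pytest.fixture
    def associations(self):
        return reference_data.load_association_table()

    def test_single_relation_mirna(self, associations):
        rel = enrichment.filter_targets(["hsa-miR-509-3p"], associations)
        assert list(rel["gene"]) == ["NTRK3"]

    def test_alias_names_resolve(self, associations):
        rel = enrichment.filter_targets(["has-miR-125b-1*"], associations)
        assert sorted(rel["gene"]) == ["IL13", "IL1B", "TNF"]

    def test_per_mirna_counts(self, associations):
        mirnas = [m for m, _a in reference_data.SIX_MIRNAS]
        rel = enrichment.filter_targets(mirnas, associations)
        counts = enrichment.per_mirna_counts(rel)
        assert counts.to_dict() == {
            "hsa-miR-125b-1-3p": 3, "hsa-miR-146a-5p": 47,
            "hsa-miR-181a-5p": 14, "hsa-miR-204-5p": 12,
            "hsa-miR-219a-5p": 5, "hsa-miR-509-3p": 1}

    def test_unknown_mirna_warns_zero_relations(self, associations):
        with pytest.warns(UserWarning, match="no relations"):
            rel = enrichment.filter_targets(["hsa-miR-000"], associations)
        assert rel.empty


class TestGeneSets:
    def test_unique_genes_deduplicates(self):
        rel = pd.DataFrame({"mirna": ["m1", "m2", "m1"],
                            "gene": ["a", "A", "B"]})
        assert enrichment.unique_genes(rel) == frozenset({"A", "B"})

    def test_unique_genes_empty(self):
        assert enrichment.unique_genes(pd.DataFrame(columns=["mirna", "gene"])) == frozenset()

    def test_mapping_partitions_input(self):
        ref = reference_data.load_pathway_reference()
        mapped, unmapped = enrichment.map_to_reference(["TNF", "NOSUCHGENE"], ref)
        assert mapped == ["TNF"] and unmapped == ["NOSUCHGENE"]

    def test_composite_symbol_maps_on_either_token(self):
        ref = reference_data.load_pathway_reference()
        mapped, unmapped = enrichment.map_to_reference(["IFNA1/IFNA13"], ref)
        assert mapped == ["IFNA1/IFNA13"] and not unmapped


class TestBinomialEnrichment:
    def test_small_worked_example(self):
        # k=2, n=3, K=2, N=10: P(X>=2) = 1 - 0.8^3 - 3*0.2*0.8^2 = 0.104
        row = enrichment.binomial_enrichment(2, 3, 2, 10, category_count=1)
        assert row.p_raw == pytest.approx(0.104)
        assert row.direction == "+"
        assert row.expected == pytest.approx(0.6)

    def test_zero_count_under_representation_closed_form(self):
        row = enrichment.binomial_enrichment(0, 20, 100, 1000, category_count=1)
        assert row.direction == "-"
        assert row.p_raw == pytest.approx(0.9 ** 20)

    def test_expected_value_matches_published_scale(self):
        row = enrichment.binomial_enrichment(7, 78, 97, 20800, category_count=6)
        assert row.expected == pytest.approx(0.36375)
        assert round(row.expected, 2) == 0.36

    def test_bonferroni_caps_at_one(self):
        row = enrichment.binomial_enrichment(1, 10, 500, 1000, category_count=1000)
        assert row.p_bonf == 1.0

    def test_invalid_category_size(self):
        with pytest.raises(ConsistencyError):
            enrichment.binomial_enrichment(1, 5, 11, 10, category_count=1)

    @pytest.mark.parametrize("k,n,K,N", [
        (2, 3, 2, 10), (0, 5, 3, 12), (5, 8, 10, 25), (4, 12, 7, 30)])
    def test_matches_exhaustive_expansion(self, k, n, K, N):
        row = enrichment.binomial_enrichment(k, n, K, N, category_count=1)
        p = K / N
        if row.direction == "+":
            assert row.p_raw == pytest.approx(exact_binomial_upper(k, n, p))
        else:
            assert row.p_raw == pytest.approx(1 - exact_binomial_upper(k + 1, n, p))

    def test_tails_share_point_mass(self):
        for k, n, K, N in [(3, 10, 4, 20), (0, 6, 2, 9), (6, 6, 5, 11)]:
            p = K / N
            upper = float(stats.binom.sf(k - 1, n, p))
            lower = float(stats.binom.cdf(k, n, p))
            assert upper + lower >= 1.0

    def test_type_one_error_control_under_uniform_sampling(self):
        """Categories drawn at the null rate reject at <= alpha."""
        rng = np.random.default_rng(2024)
        n_sims, n_target, K, N, alpha = 10_000, 40, 200, 2000, 0.05
        k_obs = rng.binomial(n_target, K / N, size=n_sims)
        expected = n_target * K / N
        p_upper = stats.binom.sf(k_obs - 1, n_target, K / N)
        p_lower = stats.binom.cdf(k_obs, n_target, K / N)
        p = np.where(k_obs > expected, p_upper, p_lower)
        rate = float((p < alpha).mean())
        mc = 3 * math.sqrt(alpha * (1 - alpha) / n_sims)
        assert rate <= alpha + mc
        # spot-check the vectorized null against the package function
        row = enrichment.binomial_enrichment(int(k_obs[0]), n_target, K, N, 1)
        assert row.p_raw == pytest.approx(
            p_upper[0] if k_obs[0] > expected else p_lower[0])


class TestFisher:
    def test_small_worked_example(self):
        universe = [f"g{i}" for i in range(10)]
        fset = universe[:5]
        sample = universe[:4]
        p = enrichment.fisher_function_enrichment(sample, fset, universe)
        assert p == pytest.approx(5 / 210)

    def test_degenerate_full_overlap(self):
        universe = ["a", "b", "c"]
        assert enrichment.fisher_function_enrichment(universe, universe, universe) == 1.0

    def test_empty_sample(self):
        universe = ["a", "b", "c", "d"]
        assert enrichment.fisher_function_enrichment([], universe[:2], universe) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_univ = int(rng.integers(5, 30))
        universe = [f"g{i}" for i in range(n_univ)]
        fset = list(rng.choice(universe, size=rng.integers(1, n_univ), replace=False))
        sample = list(rng.choice(universe, size=rng.integers(1, n_univ), replace=False))
        overlap = len(set(fset) & set(sample))
        expected = exact_hypergeom_upper(overlap, n_univ, len(fset), len(sample))
        got = enrichment.fisher_function_enrichment(sample, fset, universe)
        assert got == pytest.approx(expected)


class TestFixtureExport:
    def test_reference_tables_written_as_tsv(self, tmp_path):
        paths = reference_data.build_reference_fixtures(tmp_path)
        assoc = pd.read_csv(paths["association"], sep="\t")
        assert len(assoc) == 82
        assert assoc["synthetic"].sum() == 1
        fc = pd.read_csv(paths["foldchange"], sep="\t")
        assert fc.set_index("gene").loc["NTRK3", "fold_change"] == "170"
        ann = pd.read_csv(paths["annotation"], sep="\t")
        toll = ann[ann["category"] == "Toll receptor signaling pathway"]
        assert toll["reference_count"].iloc[0] == 56 and len(toll) == 8
        manifest = pd.read_csv(paths["manifest"], sep="\t").set_index("key")
        assert manifest.loc["universe_size", "value"] == "20800"


class TestEnrichTable:
    def test_full_reference_scoring(self):
        ref = reference_data.load_pathway_reference()
        assoc = reference_data.load_association_table()
        rel = enrichment.filter_targets([m for m, _ in reference_data.SIX_MIRNAS], assoc)
        genes = enrichment.unique_genes(rel)
        mapped, _ = enrichment.map_to_reference(genes, ref)
        table = enrichment.enrich(mapped, ref)
        assert len(table) == 6
        assert (table["direction"] == "+").all()
        assert (table["p_bonf"] >= table["p_raw"]).all()
        toll = table.set_index("category").loc["Toll receptor signaling pathway"]
        assert toll["k_obs"] == 8 and toll["k_ref"] == 56
        assert toll["expected"] == pytest.approx(78 * 56 / 20800)
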