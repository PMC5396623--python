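"""Filter miRNA targets and score pathway over-representation.

Uses the packaged association table for the six SPARC-responsive miRNAs:
the stringent experimentally-observed filter, unique-gene collapsing,
mapping into the pathway reference universe, and the Bonferroni-corrected
binomial over/under-representation test per category.
"""

from mirspot import enrichment, reference_data

mirnas = [m for m, _alias in reference_data.SIX_MIRNAS]
relations = enrichment.filter_targets(mirnas, reference_data.load_association_table())
print(f"{len(relations)} experimentally observed relations across {len(mirnas)} miRNAs:")
print(enrichment.per_mirna_counts(relations).to_string())

genes = enrichment.unique_genes(relations)
reference = reference_data.load_pathway_reference()
mapped, unmapped = enrichment.map_to_reference(genes, reference)
print(f"{len(genes)} unique genes, {len(mapped)} map into the "
      f"{reference.universe_size}-gene reference universe "
      f"(unmapped: {', '.join(unmapped)})")

table = enrichment.enrich(mapped, reference)
cols = ["category", "k_ref", "k_obs", "expected", "direction", "p_bonf", "pct"]
print(table[cols].round({"expected": 2, "pct": 2}).to_string(index=False))
# 'expected' is the count a random 78-gene list would hit in the category;
# k_obs far above it with a small Bonferroni p marks the pathway as
# over-represented among the miRNA targets.

p = enrichment.fisher_function_enrichment(
    mapped, reference.categories["Apoptosis signaling pathway"], mapped)
print(f"right-tailed Fisher score of the apoptosis set inside the mapped list: {p:.3g}")
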