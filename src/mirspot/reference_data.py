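"""Packaged reference tables for the six SPARC-responsive miRNAs.

Three small curated tables ship with the package:

* an association table of experimentally observed miRNA -> mRNA target
  relations for the six miRNAs that survive the stringent target filter
  (hsa-miR-125b-1-3p, -146a-5p, -181a-5p, -204-5p, -219a-5p, -509-3p),
  with the per-miRNA counts 3, 47, 14, 12, 5 and 1 (82 relations over 81
  unique gene symbols);
* a PANTHER-style pathway annotation reference: six signaling-pathway
  categories with their sizes in a genome-wide reference list of 20,800
  genes, plus the membership of the packaged target genes;
* a fold-change reference for the target genes in desmoplastic
  medulloblastoma versus normal cerebellum from a public tumor expression
  compendium ("ND" where no call was available).  This table is shipped
  for documentation and is never recomputed.

Synthetic stand-ins (the curated sources do not enumerate them):
the 47th miR-146a-5p relation (TNF, duplicating the miR-125b-1-3p target
so that 82 relations cover 81 unique genes); the three genes designated
unmappable against the pathway reference (TRA, ENPP6, PLEKHA4); and the
per-category gene memberships, assigned by biological role to match the
published per-category target counts.
"""

from __future__ import annotations

import pandas as pd

from .enrichment import AnnotationReference, normalize_symbol, symbol_tokens

EXP = "experimentally_observed"

#: (canonical mature name, platform alias)
SIX_MIRNAS = (
    ("hsa-miR-125b-1-3p", "has-miR-125b-1*"),
    ("hsa-miR-146a-5p", "has-miR-146a"),
    ("hsa-miR-181a-5p", "has-miR-181c"),
    ("hsa-miR-204-5p", "has-miR-204"),
    ("hsa-miR-219a-5p", "has-miR-219-5p"),
    ("hsa-miR-509-3p", "has-miR-509-3p"),
)

#: curated target genes with tumor-vs-normal fold change ("ND" = no data)
_TARGETS = {
    "hsa-miR-125b-1-3p": [
        ("TNF", "-1.15"), ("IL1B", "-4.59"), ("IL13", "-1.50"),
    ],
    "hsa-miR-219a-5p": [
        ("TNFRSF1B", "-1.54"), ("PLCG2", "27.2"), ("ENPP6", "ND"),
        ("CD14", "4.0"), ("ALOX5", "1.19"),
    ],
    "hsa-miR-509-3p": [
        ("NTRK3", "170"),
    ],
    "hsa-miR-181a-5p": [
        ("TRA", "-1.4"), ("TIMP3", "2.52"), ("TCL1A", "1.61"),
        ("NOTCH4", "1.15"), ("NLK", "-1.73"), ("KRAS", "1.10"),
        ("GRIA2", "-1.52"), ("GATA6", "7.59"), ("ESR1", "1.89"),
        ("CDX2", "32.95"), ("CDKN1B", "2.35"), ("CD69", "1.75"),
        ("BCL2", "1.55"), ("AICDA", "ND"),
    ],
    "hsa-miR-146a-5p": [
        ("TRAF6", "1.75"), ("TLR9", "ND"), ("TLR4", "1.31"), ("TLR10", "ND"),
        ("STAT1", "2.18"), ("PTGES2", "ND"), ("PLEKHA4", "ND"), ("PA2G4", "ND"),
        ("NOS2", "ND"), ("NFIX", "25.8"), ("MR1", "-1.21"), ("MMP16", "-2.35"),
        ("LTB", "1.89"), ("LBP", "ND"), ("IRAK2", "ND"), ("IRAK1", "2.96"),
        ("IL37", "ND"), ("IL36RN", "ND"), ("IL36G", "ND"), ("IL36B", "ND"),
        ("IL36A", "ND"), ("IL1RL2", "-2.0"), ("IL1RAPL2", "ND"), ("IL1RAP", "ND"),
        ("IL1R1", "-2.5"), ("IL1F10", "ND"), ("IL12RB2", "5.0"), ("IL10", "-2.92"),
        ("IFNB1", "-16.0"), ("IFNA1/IFNA13", "1.89"), ("FADD", "2.44"),
        ("CXCR4", "103"), ("CXCL8", "7.87"), ("CRP", "-1.56"),
        ("COL13A1", "-60.0"), ("CHUK", "ND"), ("CFH", "ND"), ("CDKN3", "-1.26"),
        ("CD40", "-4.0"), ("CD1D", "7.78"), ("CCR3", "-2.38"), ("CCNA2", "9.89"),
        ("CCL8", "-5.56"), ("CAMP", "2.40"), ("C8A", "1.17"), ("BRCA1", "5.29"),
    ],
    "hsa-miR-204-5p": [
        ("SOX4", "56.2"), ("SHC1", "12.7"), ("MMP9", "-1.04"), ("MMP3", "2.79"),
        ("ITGB4", "2.46"), ("HMGA2", "21.7"), ("EFNB1", "-3.4"),
        ("CDH11", "14.7"), ("CDC25B", "-3.8"), ("BMP1", "5.70"),
        ("ATP2B1", "-2.14"), ("ARPC1B", "1.89"),
    ],
}

#: synthetic filler relation completing the curated per-miRNA count of 47
#: for miR-146a-5p (duplicates TNF so 82 relations cover 81 unique genes)
_FILLER_RELATIONS = [("hsa-miR-146a-5p", "TNF")]

#: genes that do not map into the pathway reference universe (synthetic
#: designation: the curated source only reports that 3 of 81 failed to map)
UNMAPPABLE_GENES = ("TRA", "ENPP6", "PLEKHA4")

#: size of the genome-wide reference gene list behind the pathway categories
REFERENCE_UNIVERSE_SIZE = 20800

#: (category, size in reference list, member genes among the packaged targets)
_PATHWAY_CATEGORIES = (
    ("Toll receptor signaling pathway", 56,
     ("TLR4", "TLR9", "TLR10", "IRAK1", "IRAK2", "TRAF6", "LBP", "CD14")),
    ("Interleukin signaling pathway", 97,
     ("IL1B", "IL13", "IL10", "IL1R1", "IL1RAP", "IL12RB2", "IL37")),
    ("Apoptosis signaling pathway", 115,
     ("TNF", "FADD", "BCL2", "CHUK", "TNFRSF1B", "CD40")),
    ("Angiogenesis signaling pathway", 154,
     ("KRAS", "NOTCH4", "SHC1", "MMP9", "EFNB1", "STAT1")),
    ("Inflammation mediated by chemokine and cytokine signaling pathway", 245,
     ("CXCR4", "CXCL8", "CCL8", "CCR3", "IFNB1", "CRP", "LTB", "CAMP", "NOS2")),
    ("PDGF signaling pathway", 138,
     ("PLCG2", "SHC1", "STAT1", "KRAS", "GATA6")),
)


def load_association_table() -> pd.DataFrame:
    """Association table: columns ``mirna, alias, gene, evidence, synthetic``."""
    alias = dict(SIX_MIRNAS)
    rows = []
    for mirna, targets in _TARGETS.items():
        for gene, _fc in targets:
            rows.append({"mirna": mirna, "alias": alias[mirna], "gene": gene,
                         "evidence": EXP, "synthetic": False})
    for mirna, gene in _FILLER_RELATIONS:
        rows.append({"mirna": mirna, "alias": alias[mirna], "gene": gene,
                     "evidence": EXP, "synthetic": True})
    return pd.DataFrame(rows)


def load_foldchange_reference() -> pd.DataFrame:
    """Tumor-vs-normal fold changes of the curated target genes (static)."""
    rows = []
    for mirna, targets in _TARGETS.items():
        for gene, fc in targets:
            rows.append({"mirna": mirna, "gene": gene, "fold_change": fc})
    return pd.DataFrame(rows)


def load_pathway_reference() -> AnnotationReference:
    """The packaged pathway annotation reference."""
    categories = {name: frozenset(members)
                  for name, _size, members in _PATHWAY_CATEGORIES}
    ref_counts = {name: size for name, size, _members in _PATHWAY_CATEGORIES}
    universe = set()
    for targets in _TARGETS.values():
        for gene, _fc in targets:
            if normalize_symbol(gene) in UNMAPPABLE_GENES:
                continue
            universe.update(symbol_tokens(gene))
    return AnnotationReference(
        categories=categories,
        ref_counts=ref_counts,
        universe_genes=frozenset(universe),
        universe_size=REFERENCE_UNIVERSE_SIZE,
        family_size=len(_PATHWAY_CATEGORIES),
    )


def build_reference_fixtures(outdir) -> dict:
    """Write the packaged reference tables as TSVs; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    assoc = load_association_table()
    paths["association"] = outdir / "mirna_target_associations.tsv"
    assoc.to_csv(paths["association"], sep="\t", index=False)

    fc = load_foldchange_reference()
    paths["foldchange"] = outdir / "target_foldchange_reference.tsv"
    fc.to_csv(paths["foldchange"], sep="\t", index=False)

    ref = load_pathway_reference()
    rows = [{"category": name, "reference_count": ref.ref_counts[name],
             "gene": gene}
            for name in ref.categories for gene in sorted(ref.categories[name])]
    paths["annotation"] = outdir / "pathway_annotation.tsv"
    pd.DataFrame(rows).to_csv(paths["annotation"], sep="\t", index=False)

    manifest = pd.DataFrame({
        "key": ["universe_size", "family_size", "unmappable_genes"],
        "value": [ref.universe_size, ref.family_size, ",".join(UNMAPPABLE_GENES)],
    })
    paths["manifest"] = outdir / "pathway_annotation_manifest.tsv"
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
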