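"""miRNA-target filtering and category over-representation statistics.

Target relations come from a curated association table (miRNA, gene,
evidence level).  The stringent filter keeps only experimentally observed
relations, the resulting unique gene list is mapped against an annotation
reference (a PANTHER-style set of pathway categories over a genome-wide
gene universe), and each category is scored two ways:

* a binomial over/under-representation test of the category count in the
  target list against the category's share of the reference universe, with
  Bonferroni correction over the category family, and
* a right-tailed Fisher's exact (hypergeometric upper tail) score used for
  function/disease signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ConsistencyError

EVIDENCE_LEVELS = ("experimentally_observed", "high_confidence_predicted", "predicted")
_EVIDENCE_RANK = {name: i for i, name in enumerate(EVIDENCE_LEVELS)}


@dataclass
class AnnotationReference:
    """Pathway/function categories over a reference gene universe.

    ``categories`` maps each category to its known member genes (within the
    universe); ``ref_counts`` carries the category size in the full
    reference list (which may be far larger than the genes enumerated
    here); ``universe_size`` is the size of the whole reference list and
    ``family_size`` the Bonferroni multiplier for the tested family.
    ``universe_genes`` enumerates the genes known to be mappable.
    """

    categories: dict
    ref_counts: dict
    universe_genes: frozenset
    universe_size: int
    family_size: int

    def __post_init__(self):
        for name, members in self.categories.items():
            k = self.ref_counts.get(name, len(members))
            if len(members) > k:
                raise ConsistencyError(
                    f"category {name!r} enumerates more genes than its reference count"
                )
            if k > self.universe_size:
                raise ConsistencyError(
                    f"category {name!r} larger than the reference universe"
                )


@dataclass
class EnrichmentRow:
    """One category's over/under-representation result."""

    category: str
    k_ref: int          # reference genes in the category
    k_obs: int          # target genes in the category
    n_target: int
    expected: float     # n_target * k_ref / universe_size
    pct: float          # 100 * k_obs / n_target
    direction: str      # '+' over-represented, '-' under-represented
    p_raw: float
    p_bonf: float


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def symbol_tokens(symbol: str) -> tuple:
    """Tokens of a possibly composite symbol such as ``IFNA1/IFNA13``."""
    return tuple(t for t in normalize_symbol(symbol).split("/") if t)


def filter_targets(mirnas, relations: pd.DataFrame,
                   evidence: str = "experimentally_observed") -> pd.DataFrame:
    """Relations for the queried miRNAs at or above an evidence level.

    miRNA names are matched case-insensitively against the ``mirna`` column
    and an optional ``alias`` column (array platforms and databases often
    disagree on mature-name spelling).  A queried miRNA without any relation
    triggers a warning and contributes nothing.
    """
    if evidence not in _EVIDENCE_RANK:
        raise ConsistencyError(f"unknown evidence level {evidence!r}")
    max_rank = _EVIDENCE_RANK[evidence]
    names = {}
    for _, row in relations.iterrows():
        names.setdefault(row["mirna"].lower(), row["mirna"])
        if "alias" in relations.columns and isinstance(row.get("alias"), str):
            names.setdefault(row["alias"].lower(), row["mirna"])
    keep = []
    for query in mirnas:
        canonical = names.get(str(query).lower())
        if canonical is None:
            warnings.warn(f"miRNA {query!r} has no relations in the association table")
            continue
        keep.append(canonical)
    sub = relations[
        relations["mirna"].isin(keep)
        & (relations["evidence"].map(_EVIDENCE_RANK) <= max_rank)
    ]
    return sub.reset_index(drop=True)


def per_mirna_counts(relations: pd.DataFrame) -> pd.Series:
    return relations.groupby("mirna").size().sort_index()


def unique_genes(relations: pd.DataFrame) -> frozenset:
    """Case-normalized distinct gene symbols across relations."""
    if relations.empty:
        return frozenset()
    return frozenset(normalize_symbol(g) for g in relations["gene"])


def map_to_reference(genes, reference: AnnotationReference):
    """Partition genes by membership in the reference universe.

    A composite symbol maps when either of its tokens is in the universe.
    Returns ``(mapped, unmapped)`` as sorted lists of the input symbols.
    """
    mapped, unmapped = [], []
    for gene in sorted(genes):
        toks = symbol_tokens(gene)
        if any(t in reference.universe_genes for t in toks):
            mapped.append(normalize_symbol(gene))
        else:
            unmapped.append(normalize_symbol(gene))
    return mapped, unmapped


def binomial_enrichment(k_obs: int, n_target: int, k_ref: int, n_ref: int,
                        category_count: int, category: str = "") -> EnrichmentRow:
    """Binomial tail test of a category's count in the target list.

    With category probability ``p = k_ref / n_ref`` and ``X ~
    Binomial(n_target, p)``: over-representation is ``P(X >= k_obs)`` and
    under-representation ``P(X <= k_obs)``; the reported tail follows the
    direction of ``k_obs`` relative to the expectation ``n_target * p``.
    Bonferroni correction multiplies by the family size, capped at 1.
    """
    if k_ref > n_ref:
        raise ConsistencyError("category cannot exceed the reference universe")
    if not 0 <= k_obs <= n_target:
        raise ConsistencyError("observed count must lie in [0, n_target]")
    p_cat = k_ref / n_ref
    expected = n_target * p_cat
    if k_obs > expected:
        direction = "+"
        p_raw = float(stats.binom.sf(k_obs - 1, n_target, p_cat))
    else:
        direction = "-"
        p_raw = float(stats.binom.cdf(k_obs, n_target, p_cat))
    return EnrichmentRow(
        category=category,
        k_ref=k_ref,
        k_obs=k_obs,
        n_target=n_target,
        expected=expected,
        pct=100.0 * k_obs / n_target if n_target else 0.0,
        direction=direction,
        p_raw=p_raw,
        p_bonf=min(1.0, p_raw * category_count),
    )


def enrich(genes, reference: AnnotationReference) -> pd.DataFrame:
    """Score every reference category against a mapped gene list."""
    gene_set = {normalize_symbol(g) for g in genes}
    rows = []
    for name in reference.categories:
        members = {normalize_symbol(g) for g in reference.categories[name]}
        k_obs = len(gene_set & members)
        row = binomial_enrichment(
            k_obs=k_obs,
            n_target=len(gene_set),
            k_ref=reference.ref_counts[name],
            n_ref=reference.universe_size,
            category_count=reference.family_size,
            category=name,
        )
        rows.append(vars(row))
    out = pd.DataFrame(rows)
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def fisher_function_enrichment(genes, function_set, universe) -> float:
    """Right-tailed Fisher's exact probability of the observed overlap.

    Hypergeometric upper tail: probability of drawing at least the observed
    number of function-set genes when ``len(genes)`` genes are sampled
    without replacement from the universe.
    """
    universe = {normalize_symbol(g) for g in universe}
    genes = {normalize_symbol(g) for g in genes} & universe
    function_set = {normalize_symbol(g) for g in function_set} & universe
    overlap = len(genes & function_set)
    n_univ = len(universe)
    return float(stats.hypergeom.sf(overlap - 1, n_univ, len(function_set), len(genes)))
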