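"""Signature-sharing enrichment between datasets and against reference sets.

Sharing between two clusterings is tested pairwise with one-sided Fisher
exact tests on 2x2 overlap tables over an explicit gene universe, with
Benjamini-Hochberg correction across pairs.  Pairs sharing fewer than
``min_overlap`` genes (default 10) are reported with statistics but
flagged and excluded from the BH family and from significance calls.
Cross-species comparisons first restrict signatures to 1:1 orthologs.

Each result carries a tier: ``significant`` (FDR < 0.01 by default),
``marginal`` (FDR in [0.01, 0.05)), ``ns`` or ``excluded``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import GeneSet, OrthologMap, ValidationError
from .stats import bh_adjust, fisher_one_sided  # noqa: F401

__all__ = [
    "EnrichmentResult",
    "restrict_to_one_to_one",
    "fisher_one_sided",
    "signature_sharing",
    "external_set_enrichment",
]

MARGINAL_FDR = 0.05


@dataclass
class EnrichmentResult:
    query_set: str
    reference_set: str
    universe_size: int
    overlap_genes: frozenset[str]
    fisher_p: float
    q_value: float = float("nan")
    passed_min_overlap: bool = True
    tier: str = "ns"

    @property
    def overlap_count(self) -> int:
        return len(self.overlap_genes)


def restrict_to_one_to_one(
    gene_set: GeneSet, ortholog_map: OrthologMap, direction: str = "a2b"
) -> tuple[GeneSet, frozenset[str]]:
    """Translate a gene set through the 1:1 ortholog subset.

    Genes with mapping degree 1 on both sides are translated; every other
    gene (unmapped or 1:many/many:1) is dropped.  Returns the translated
    set and the set of dropped input genes.
    """
    table = ortholog_map.one_to_one(direction)
    kept = {table[g] for g in gene_set.genes if g in table}
    dropped = frozenset(g for g in gene_set.genes if g not in table)
    return (
        GeneSet(name=gene_set.name, genes=frozenset(kept), source_tag=gene_set.source_tag),
        dropped,
    )


def _overlap_table(
    query: frozenset[str], reference: frozenset[str], universe: frozenset[str]
) -> list[list[int]]:
    a = len(query & reference)
    b = len(query - reference)
    c = len(reference - query)
    d = len(universe) - a - b - c
    return [[a, b], [c, d]]


def _tier(q: float, fdr: float) -> str:
    if q < fdr:
        return "significant"
    if q < MARGINAL_FDR:
        return "marginal"
    return "ns"


def signature_sharing(
    query_sets: Sequence[GeneSet] | GeneSet,
    reference_sets: Sequence[GeneSet] | GeneSet,
    universe: Iterable[str],
    min_overlap: int = 10,
    fdr: float = 0.01,
) -> list[EnrichmentResult]:
    """All-pairs sharing enrichment between two collections of signatures.

    Every (query, reference) pair gets a one-sided Fisher test on the 2x2
    in/out-of-query x in/out-of-reference table over ``universe``.  BH
    spans the pairs meeting ``min_overlap``; pairs below it keep their raw
    p but are tiered ``excluded``.
    """
    if isinstance(query_sets, GeneSet):
        query_sets = [query_sets]
    if isinstance(reference_sets, GeneSet):
        reference_sets = [reference_sets]
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise ValidationError("empty gene universe")
    for gs in (*query_sets, *reference_sets):
        stray = gs.genes - universe
        if stray:
            raise ValidationError(
                f"set {gs.name!r} has genes outside the universe: "
                f"{sorted(stray)[:5]}"
            )
    results: list[EnrichmentResult] = []
    for q_set in query_sets:
        for r_set in reference_sets:
            overlap = frozenset(q_set.genes & r_set.genes)
            p = fisher_one_sided(
                _overlap_table(q_set.genes, r_set.genes, universe)
            ).p_value
            results.append(
                EnrichmentResult(
                    query_set=q_set.name,
                    reference_set=r_set.name,
                    universe_size=len(universe),
                    overlap_genes=overlap,
                    fisher_p=p,
                    passed_min_overlap=len(overlap) >= min_overlap,
                )
            )
    in_family = [r for r in results if r.passed_min_overlap]
    if in_family:
        qs = bh_adjust([r.fisher_p for r in in_family])
        for r, q in zip(in_family, qs):
            r.q_value = float(q)
            r.tier = _tier(r.q_value, fdr)
    for r in results:
        if not r.passed_min_overlap:
            r.tier = "excluded"
    return results


def external_set_enrichment(
    cluster_signature: GeneSet,
    reference_sets: Sequence[GeneSet],
    universe: Iterable[str],
    fdr: float = 0.01,
) -> list[EnrichmentResult]:
    """Enrichment of one cluster signature against reference gene sets
    (GO terms, published cell-state programs, fetal/external markers).

    One Fisher test per reference set, BH across the sets; no minimum
    overlap filter.  Reference genes outside the universe are ignored.
    """
    universe = frozenset(str(g) for g in universe)
    if not universe:
        raise ValidationError("empty gene universe")
    query = cluster_signature.genes & universe
    if cluster_signature.genes - universe:
        raise ValidationError(
            f"signature {cluster_signature.name!r} has genes outside the universe"
        )
    results: list[EnrichmentResult] = []
    for r_set in reference_sets:
        ref = r_set.genes & universe
        overlap = frozenset(query & ref)
        p = fisher_one_sided(_overlap_table(query, ref, universe)).p_value
        results.append(
            EnrichmentResult(
                query_set=cluster_signature.name,
                reference_set=r_set.name,
                universe_size=len(universe),
                overlap_genes=overlap,
                fisher_p=p,
            )
        )
    if results:
        qs = bh_adjust([r.fisher_p for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
            r.tier = _tier(r.q_value, fdr)
    return results
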