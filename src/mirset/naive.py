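"""Hash-set reference engine.

This is the classical implementation strategy: gene sets as hash tables,
unions by folding, intersection *sizes* by hash-join probing of the smaller
(category) side — the output intersection set itself is never produced,
since only its size is needed. It is exact and deliberately simple, so it
serves as the independent oracle for the bitset engine: given the same
sampled groups it must produce identical exceed counts, p-values and output
files. It is also exposed as a first-class CLI engine so the equivalence is
user-verifiable.
"""

from __future__ import annotations

from .bitsets import OpCounters
from .errors import LogicError
from .io import AnnotationTable, InteractionTable
from .result import EnrichmentResult


def hash_union(sets: list[set], counters: OpCounters | None = None) -> set:
    """Fold member sets into an initially empty accumulator; one op per member."""
    acc: set = set()
    for s in sets:
        acc |= s
    if counters is not None:
        counters.union_ops += len(sets)
    return acc


def hash_join_size(group: set, category_genes: list, counters: OpCounters | None = None) -> int:
    """Intersection size by probing each category gene into the group's hash table."""
    if counters is not None:
        counters.probe_ops += len(category_genes)
    return sum(1 for g in category_genes if g in group)


def naive_engine(
    kept_query: list[str],
    interactions: InteractionTable,
    annotations: AnnotationTable,
    groups: list[tuple[str, ...]],
    config,
    counters: OpCounters,
) -> tuple[list[EnrichmentResult], int]:
    """Run the full per-category analysis with plain hash sets.

    Mirrors the bitset engine's semantics exactly: same universe filtering,
    same zero-overlap exclusion, same comparison convention, same category
    order.
    """
    targets: dict[str, set[str]] = {}
    for m, g in interactions.entries:
        targets.setdefault(m, set()).add(g)

    universe = {g for _, g in interactions.entries}
    if config.include_annotation_only_genes:
        universe |= {g for g, _, _ in annotations.entries}

    # categories in sorted-id order, genes filtered to the universe and sorted
    raw: dict[str, tuple[str, set[str]]] = {}
    for gene, cat_id, name in annotations.entries:
        nm, genes = raw.setdefault(cat_id, (name, set()))
        if gene in universe:
            genes.add(gene)
    cats = [
        (cid, raw[cid][0], sorted(raw[cid][1])) for cid in sorted(raw) if raw[cid][1]
    ]

    try:
        query_set = hash_union([targets[m] for m in kept_query], counters)
    except KeyError as exc:
        raise LogicError(f"query miRNA {exc} has no target set") from exc

    query_overlaps = [hash_join_size(query_set, genes, counters) for _, _, genes in cats]

    pool_sets = [hash_union([targets[m] for m in g], counters) for g in groups]
    n = len(groups)

    results: list[EnrichmentResult] = []
    for (cid, name, genes), q in zip(cats, query_overlaps):
        exceed = p = None
        if q > 0:
            hits = [hash_join_size(s, genes, counters) for s in pool_sets]
            if config.strict_greater:
                exceed = sum(1 for h in hits if h > q)
            else:
                exceed = sum(1 for h in hits if h >= q)
            p = (exceed + 1) / (n + 1) if config.plus_one_correction else exceed / n
        results.append(
            EnrichmentResult(
                category_id=cid,
                category_name=name,
                category_size=len(genes),
                overlap_count=q,
                overlap_proportion=q / len(genes),
                exceed_count=exceed,
                empirical_p=p,
            )
        )
    return results, len(universe)
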