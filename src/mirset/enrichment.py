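"""Monte Carlo empirical p-values for miRNA-group functional enrichment.

The statistic per annotation category is the *biological process overlap*:
the intersection between the union of the query group's predicted targets
and the category's gene set. Its null distribution is obtained by sampling
N random miRNA groups of the query's size from all miRNAs in the interaction
table; the empirical p-value is the fraction of random groups whose overlap
exceeds the query's (strictly greater, by default).

One random pool is sampled per run and its union bitsets are materialized
once, shared read-only across all categories and workers; categories sharing
no gene with the query's targets are excluded from testing and reported
with an NA p-value. Results are bit-identical for any worker count at a
fixed seed because all randomness happens before the parallel section.
"""

from __future__ import annotations

import itertools
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import naive
from .bitsets import (
    CategoryIndex,
    OpCounters,
    TargetBitset,
    UniverseConfig,
    build_universe,
    category_indexes,
    group_union,
    mirna_bitsets,
    probe_overlap,
    stack_bitsets,
)
from .errors import LogicError
from .io import AnnotationTable, InteractionTable, QueryGroup
from .result import EnrichmentResult, sort_key
from .stats import bh_mark

logger = logging.getLogger(__name__)

#: an ordered tuple of distinct miRNA identifiers
MiRNAGroup = tuple[str, ...]

#: accuracy presets: more random groups = finer, more accurate p-value grid
ITERATION_PRESETS = {"10K": 10_000, "100K": 100_000, "1M": 1_000_000}

DEFAULT_SEED = 17


@dataclass
class RunConfig:
    """Parameters of one enrichment run."""

    iterations: int = ITERATION_PRESETS["10K"]
    seed: int = DEFAULT_SEED
    workers: int = 1
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    #: count random groups with overlap strictly greater than the query's;
    #: False counts >= instead
    strict_greater: bool = True
    #: report (k+1)/(N+1) instead of k/N, avoiding p = 0
    plus_one_correction: bool = False
    engine: str = "bitset"  # or "naive" (hash-set reference implementation)
    exclude_query_from_null: bool = False
    include_annotation_only_genes: bool = False

    def __post_init__(self):
        if self.iterations < 1:
            raise LogicError("iterations must be >= 1")
        if self.workers < 1:
            raise LogicError("workers must be >= 1")
        a1, a2 = self.alpha_levels
        if not (0 < a2 < a1 < 1):
            raise LogicError("alpha levels must satisfy 0 < alpha2 < alpha1 < 1")
        if self.engine not in ("bitset", "naive"):
            raise LogicError(f"unknown engine {self.engine!r}")


@dataclass
class RandomGroupPool:
    """N random miRNA groups with their union bitsets, materialized once.

    The union bitsets are stored as one (N, words) uint64 matrix so the
    per-category probing can be vectorized; ``union_bitsets`` exposes the
    rows as individual bitset views.
    """

    groups: list[MiRNAGroup]
    matrix: np.ndarray
    n_bits: int

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def union_bitsets(self) -> list[TargetBitset]:
        return [TargetBitset(self.n_bits, row) for row in self.matrix]


@dataclass
class RunReport:
    """Machine-readable account of one enrichment run."""

    engine: str = "bitset"
    seed: int = DEFAULT_SEED
    iterations: int = 0
    workers: int = 1
    group_size: int = 0
    universe_size: int = 0
    n_categories: int = 0
    n_tested: int = 0
    n_excluded: int = 0
    m: int = 0  # categories entering the FDR correction (= n_tested)
    union_ops: int = 0
    probe_ops: int = 0
    dropped_query_mirnas: list[str] = field(default_factory=list)
    elapsed_seconds: float = 0.0


def sample_groups(
    all_mirnas: list[str], size: int, n: int, seed: int
) -> list[MiRNAGroup]:
    """Draw n uniform without-replacement miRNA groups of the given size.

    Groups may repeat across draws; the list is fully determined by the seed.
    """
    if size < 1:
        raise LogicError("group size must be >= 1")
    if size > len(all_mirnas):
        raise LogicError(
            f"group size {size} exceeds the {len(all_mirnas)} available miRNAs"
        )
    rng = np.random.default_rng(seed)
    pop = np.asarray(all_mirnas, dtype=object)
    k = len(all_mirnas)
    return [tuple(pop[rng.choice(k, size=size, replace=False)]) for _ in range(n)]


def all_groups(all_mirnas: list[str], size: int) -> list[MiRNAGroup]:
    """Every possible group of the given size (exhaustive-null mode)."""
    return [tuple(c) for c in itertools.combinations(sorted(all_mirnas), size)]


def build_pool(
    groups: list[MiRNAGroup],
    bitsets: dict[str, TargetBitset],
    counters: OpCounters | None = None,
    chunk: int = 4096,
) -> RandomGroupPool:
    """Union bitset per group, computed by chunked vectorized bitwise-or.

    Counts one union fold step per group member (N x size in total).
    """
    if not groups:
        raise LogicError("cannot build a pool from zero groups")
    size = len(groups[0])
    if any(len(g) != size for g in groups):
        raise LogicError("all pool groups must have the query group's size")
    order = sorted(bitsets)
    row = {m: i for i, m in enumerate(order)}
    try:
        idx = np.array([[row[m] for m in g] for g in groups], dtype=np.intp)
    except KeyError as exc:
        raise LogicError(f"group member {exc} has no target bitset") from exc
    stacked = stack_bitsets(bitsets, order)
    parts = [
        np.bitwise_or.reduce(stacked[idx[s : s + chunk]], axis=1)
        for s in range(0, len(groups), chunk)
    ]
    if counters is not None:
        counters.union_ops += len(groups) * size
    return RandomGroupPool(groups, np.concatenate(parts), bitsets[order[0]].n_bits)


def pool_overlaps(
    pool: RandomGroupPool, category: CategoryIndex, counters: OpCounters | None = None
) -> np.ndarray:
    """Bit-probe every pool bitset against the category; one probe per gene."""
    pos = category.gene_bits
    if pos.size and int(pos[-1]) >= pool.n_bits:
        raise LogicError("category position outside the pool's universe")
    bits = (pool.matrix[:, pos >> 6] >> (pos & 63).astype(np.uint64)) & np.uint64(1)
    if counters is not None:
        counters.probe_ops += pool.n * category.size
    return bits.sum(axis=1).astype(np.int64)


def empirical_pvalue(
    query_overlap: int,
    pool: RandomGroupPool,
    category: CategoryIndex,
    config: RunConfig,
    counters: OpCounters | None = None,
) -> tuple[int, float]:
    """(exceed_count, p) for one tested category.

    exceed_count counts pool groups whose overlap is strictly greater than
    (or >= , per config) the query's; comparing counts is equivalent to
    comparing proportions because the category size is a per-category
    constant.
    """
    ov = pool_overlaps(pool, category, counters)
    exceed = int((ov > query_overlap).sum() if config.strict_greater else (ov >= query_overlap).sum())
    n = pool.n
    p = (exceed + 1) / (n + 1) if config.plus_one_correction else exceed / n
    return exceed, p


def _partition(items: list, workers: int) -> list[list]:
    """Contiguous near-equal chunks; at most `workers` of them."""
    k = min(workers, len(items)) or 1
    bounds = np.linspace(0, len(items), k + 1).astype(int)
    return [items[bounds[i] : bounds[i + 1]] for i in range(k) if bounds[i] < bounds[i + 1]]


def _bitset_engine(kept_query, interactions, annotations, groups, config, counters):
    """The fast path: bitwise-or unions, bit-probing intersection counts."""
    universe = build_universe(
        interactions,
        annotations,
        UniverseConfig(config.include_annotation_only_genes),
    )
    bitsets = mirna_bitsets(interactions, universe)
    cats = category_indexes(annotations, universe)

    query_union = group_union([bitsets[m] for m in kept_query], counters)
    query_overlaps = [probe_overlap(query_union, c, counters) for c in cats]
    tested = [(i, c, q) for (i, c), q in zip(enumerate(cats), query_overlaps) if q > 0]

    pool = build_pool(groups, bitsets, counters)

    def work(chunk):
        local = OpCounters()
        return [
            (i, *empirical_pvalue(q, pool, c, config, local)) for i, c, q in chunk
        ], local

    chunks = _partition(tested, config.workers)
    if config.workers > 1 and len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as ex:
            outputs = list(ex.map(work, chunks))
    else:
        outputs = [work(c) for c in chunks]

    pvals: dict[int, tuple[int, float]] = {}
    for triples, local in outputs:
        counters.merge(local)
        for i, exceed, p in triples:
            pvals[i] = (exceed, p)

    results = []
    for i, (c, q) in enumerate(zip(cats, query_overlaps)):
        exceed, p = pvals.get(i, (None, None))
        results.append(
            EnrichmentResult(
                category_id=c.category_id,
                category_name=c.name,
                category_size=c.size,
                overlap_count=q,
                overlap_proportion=q / c.size,
                exceed_count=exceed,
                empirical_p=p,
            )
        )
    return results, universe.size


def run_enrichment(
    query: QueryGroup,
    interactions: InteractionTable,
    annotations: AnnotationTable,
    config: RunConfig | None = None,
    groups: list[MiRNAGroup] | None = None,
) -> tuple[list[EnrichmentResult], RunReport]:
    """Full analysis: sample the null pool, test every category, mark FDR.

    Query miRNAs absent from the interaction table are dropped with a
    warning (fatal if none remain). Passing `groups` explicitly replaces
    Monte Carlo sampling with the given null groups (e.g. the exhaustive
    enumeration of all possible groups).
    """
    config = config or RunConfig()
    t0 = time.perf_counter()

    known = set(m for m, _ in interactions.entries)
    kept = [m for m in query.mirna_ids if m in known]
    dropped = [m for m in query.mirna_ids if m not in known]
    if dropped:
        logger.warning("query miRNAs absent from the interaction table: %s", dropped)
    if not kept:
        raise LogicError("no query miRNA appears in the interaction table")

    if groups is None:
        population = interactions.mirna_ids()
        if config.exclude_query_from_null:
            population = [m for m in population if m not in set(kept)]
        groups = sample_groups(population, len(kept), config.iterations, config.seed)

    counters = OpCounters()
    if config.engine == "naive":
        results, universe_size = naive.naive_engine(
            kept, interactions, annotations, groups, config, counters
        )
    else:
        results, universe_size = _bitset_engine(
            kept, interactions, annotations, groups, config, counters
        )

    marked = bh_mark(results, config.alpha_levels)
    results = sorted(marked.results, key=sort_key)
    n_tested = marked.m
    report = RunReport(
        engine=config.engine,
        seed=config.seed,
        iterations=len(groups),
        workers=config.workers,
        group_size=len(kept),
        universe_size=universe_size,
        n_categories=len(results),
        n_tested=n_tested,
        n_excluded=len(results) - n_tested,
        m=n_tested,
        union_ops=counters.union_ops,
        probe_ops=counters.probe_ops,
        dropped_query_mirnas=dropped,
        elapsed_seconds=time.perf_counter() - t0,
    )
    if n_tested == 0:
        logger.warning("query targets share no gene with any category; nothing tested")
    return results, report
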