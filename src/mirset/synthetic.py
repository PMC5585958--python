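"""Synthetic interaction / annotation / query generator.

Emulates the statistical regime of genome-scale miRNA target-prediction
exports: per-miRNA target counts are strongly right-skewed (a handful of
targets for some miRNAs, thousands for others — mean well above the median),
so the counts follow a rounded log-normal law truncated to a configured
range. Correlation between miRNA target sets — the structural bias that
makes gene-level Fisher tests anti-conservative for miRNA groups — is
induced by a shared "hub" gene pool that every miRNA preferentially targets:
each miRNA draws ``Binomial(count, shared_pool_fraction)`` of its targets
from the hub pool and the rest uniformly from the remaining genes. At
``shared_pool_fraction = 0`` this reduces exactly to uniform target sampling.

Annotation categories are uniform random gene sets of small-to-moderate
size. A *planted* configuration constructs the query group so that its
target union covers a requested fraction of one category, giving a
known-enriched instance for end-to-end tests.

What this generator does not emulate: real miRNA/gene nomenclature,
prediction-score distributions, the GO DAG, or gene-length/expression
confounders; see the methods note for the implications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import InputError, LogicError
from .io import AnnotationTable, InteractionTable, QueryGroup

_LOG64 = math.log(64.0)


@dataclass
class TargetCountLaw:
    """Rounded log-normal law for per-miRNA target counts, truncated to
    [min_targets, max_targets].

    Defaults give a median around 64 targets with a heavy right tail
    (mean several times the median), the regime of genome-scale prediction
    exports.
    """

    log_mean: float = _LOG64
    log_sd: float = 1.9
    min_targets: int = 5
    max_targets: int = 4000

    def sample(self, rng: np.random.Generator, n: int, n_genes: int) -> np.ndarray:
        hi = min(self.max_targets, n_genes)
        raw = np.rint(np.exp(rng.normal(self.log_mean, self.log_sd, size=n)))
        return np.clip(raw, self.min_targets, hi).astype(np.int64)

    def expected_count(self, n_genes: int) -> float:
        """Exact mean of the rounded, truncated law (analytic oracle)."""
        hi = min(self.max_targets, n_genes)
        lo = self.min_targets
        ks = np.arange(lo, hi + 1, dtype=np.float64)
        upper = norm.cdf((np.log(ks + 0.5) - self.log_mean) / self.log_sd)
        lower = norm.cdf((np.log(np.maximum(ks - 0.5, 1e-12)) - self.log_mean) / self.log_sd)
        pmf = upper - lower
        # clipping piles the tails onto the endpoints
        pmf[0] += lower[0]
        pmf[-1] += 1.0 - upper[-1]
        return float((ks * pmf).sum())

    def variance(self, n_genes: int) -> float:
        hi = min(self.max_targets, n_genes)
        lo = self.min_targets
        ks = np.arange(lo, hi + 1, dtype=np.float64)
        upper = norm.cdf((np.log(ks + 0.5) - self.log_mean) / self.log_sd)
        lower = norm.cdf((np.log(np.maximum(ks - 0.5, 1e-12)) - self.log_mean) / self.log_sd)
        pmf = upper - lower
        pmf[0] += lower[0]
        pmf[-1] += 1.0 - upper[-1]
        mu = float((ks * pmf).sum())
        return float((ks * ks * pmf).sum() - mu * mu)


@dataclass
class PlantedSignal:
    """Construct the query so its target union covers part of one category."""

    category_id: str
    query_size: int
    coverage_fraction: float


@dataclass
class ScenarioConfig:
    n_mirnas: int = 500
    n_genes: int = 5000
    target_count_law: TargetCountLaw = field(default_factory=TargetCountLaw)
    #: expected fraction of each miRNA's targets drawn from the shared hub pool
    shared_pool_fraction: float = 0.3
    #: fraction of genes forming the hub pool
    hub_pool_fraction: float = 0.1
    n_categories: int = 50
    category_size_law: tuple[int, int] = (10, 100)
    #: fraction of each category's genes drawn from the hub pool (0 = uniform).
    #: Real annotations are enriched for highly targeted genes; this knob
    #: reproduces that annotation-structure bias, which is what makes the
    #: gene-level hypergeometric test anti-conservative for miRNA groups.
    category_hub_bias: float = 0.0
    planted: PlantedSignal | None = None
    query_size: int = 10
    seed: int = 0

    def __post_init__(self):
        # a max_targets above n_genes is capped at sampling time
        if self.target_count_law.min_targets < 1:
            raise LogicError("min_targets must be >= 1")
        if not (0 <= self.shared_pool_fraction < 1):
            raise LogicError("shared_pool_fraction must lie in [0, 1)")
        if not (0 <= self.category_hub_bias <= 1):
            raise LogicError("category_hub_bias must lie in [0, 1]")
        if self.category_size_law[1] > self.n_genes:
            raise LogicError("category sizes cannot exceed the number of genes")


@dataclass
class Truth:
    """Every draw the generator made, for bookkeeping assertions."""

    gene_ids: list[str]
    mirna_ids: list[str]
    hub_genes: list[str]
    targets: dict[str, list[str]]             # miRNA -> sorted target genes
    categories: dict[str, tuple[str, list[str]]]  # id -> (name, sorted genes)
    query: list[str]
    planted_coverage: float | None = None     # realized fraction of the planted category


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[InteractionTable, AnnotationTable, QueryGroup, Truth]:
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i:04d}" for i in range(config.n_mirnas)]
    gene_arr = np.asarray(genes, dtype=object)

    s = config.shared_pool_fraction
    n_hub = max(1, round(config.hub_pool_fraction * config.n_genes)) if s > 0 else 0
    hub_idx = rng.choice(config.n_genes, size=n_hub, replace=False) if n_hub else np.array([], dtype=np.int64)
    hub_set = set(hub_idx.tolist())
    non_hub_idx = np.array([i for i in range(config.n_genes) if i not in hub_set], dtype=np.int64)

    counts = config.target_count_law.sample(rng, config.n_mirnas, config.n_genes)
    targets: dict[str, set[str]] = {}
    for m, c in zip(mirnas, counts):
        c = int(c)
        k_hub = min(int(rng.binomial(c, s)), n_hub, c) if n_hub else 0
        chosen = rng.choice(hub_idx, size=k_hub, replace=False) if k_hub else np.array([], dtype=np.int64)
        rest_pool = non_hub_idx if k_hub == n_hub else np.setdiff1d(
            np.arange(config.n_genes), chosen, assume_unique=False
        )
        k_rest = min(c - k_hub, rest_pool.size)
        rest = rng.choice(rest_pool, size=k_rest, replace=False)
        targets[m] = set(gene_arr[np.concatenate([chosen, rest])].tolist())

    sizes = rng.integers(config.category_size_law[0], config.category_size_law[1] + 1,
                         size=config.n_categories)
    categories: dict[str, tuple[str, list[str]]] = {}
    for j, sz in enumerate(sizes):
        cid = f"CAT:{j:04d}"
        sz = int(sz)
        k_hub_cat = min(round(config.category_hub_bias * sz), n_hub)
        from_hub = rng.choice(hub_idx, size=k_hub_cat, replace=False) if k_hub_cat else np.array([], dtype=np.int64)
        rest_pool = np.setdiff1d(np.arange(config.n_genes), from_hub, assume_unique=False)
        rest = rng.choice(rest_pool, size=sz - k_hub_cat, replace=False)
        members = gene_arr[np.concatenate([from_hub, rest])]
        categories[cid] = (f"process-{j:04d}", sorted(members.tolist()))

    planted_coverage = None
    if config.planted is not None:
        pl = config.planted
        if pl.category_id not in categories:
            raise LogicError(f"planted category {pl.category_id!r} does not exist")
        if not (0 <= pl.coverage_fraction <= 1) or pl.query_size < 1:
            raise LogicError("infeasible planting: need 0 <= coverage <= 1 and query_size >= 1")
        if pl.query_size > config.n_mirnas:
            raise LogicError("infeasible planting: query_size exceeds the miRNA count")
        cat_genes = categories[pl.category_id][1]
        need = math.ceil(pl.coverage_fraction * len(cat_genes))
        query = [mirnas[i] for i in rng.choice(config.n_mirnas, size=pl.query_size, replace=False)]
        picked = [cat_genes[i] for i in rng.choice(len(cat_genes), size=need, replace=False)]
        for i, g in enumerate(picked):  # round-robin injection into the query's targets
            targets[query[i % len(query)]].add(g)
        union = set().union(*(targets[m] for m in query))
        planted_coverage = len(union & set(cat_genes)) / len(cat_genes)
    else:
        if config.query_size > config.n_mirnas:
            raise LogicError("query_size exceeds the miRNA count")
        query = [mirnas[i] for i in rng.choice(config.n_mirnas, size=config.query_size, replace=False)]

    sorted_targets = {m: sorted(ts) for m, ts in targets.items()}
    interactions = InteractionTable(
        [(m, g) for m in mirnas for g in sorted_targets[m]]
    )
    annotations = AnnotationTable(
        [(g, cid, categories[cid][0]) for cid in sorted(categories) for g in categories[cid][1]]
    )
    truth = Truth(
        gene_ids=genes,
        mirna_ids=mirnas,
        hub_genes=sorted(gene_arr[hub_idx].tolist()),
        targets=sorted_targets,
        categories=categories,
        query=query,
        planted_coverage=planted_coverage,
    )
    return interactions, annotations, QueryGroup(query), truth


def write_scenario(
    interactions: InteractionTable,
    annotations: AnnotationTable,
    query: QueryGroup,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the three input files in the package's own input formats."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": d / "interactions.csv",
            "annotations": d / "annotations.csv",
            "query": d / "query.txt",
        }
        with open(paths["interactions"], "w", encoding="utf-8") as fh:
            for m, g in interactions.entries:
                fh.write(f"{m},{g}\n")
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            for g, cid, name in annotations.entries:
                fh.write(f"{g},{cid},{name}\n")
        with open(paths["query"], "w", encoding="utf-8") as fh:
            for m in query.mirna_ids:
                fh.write(m + "\n")
    except OSError as exc:
        raise InputError(f"cannot write scenario to {d}: {exc}") from exc
    return paths
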