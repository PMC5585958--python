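"""Multiple-testing marking and the classic hypergeometric comparator.

Empirical p-values are marked by Benjamini-Hochberg step-up FDR control at
two nested levels (default 0.05 -> "*", 0.01 -> "**"). Excluded (NA)
categories carry no mark and do not count toward the number of tests.

The one-sided hypergeometric tail (Fisher's exact test for
over-representation) is provided as the biased gene-level baseline that the
Monte Carlo empirical p-value corrects: with correlated miRNA target sets it
declares significance for randomly assembled miRNA groups far more often
than its nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .bitsets import CategoryIndex, TargetBitset, popcount_overlap
from .result import EnrichmentResult


@dataclass
class MarkedResults:
    results: list[EnrichmentResult]
    m: int  # number of tested (non-NA) categories


def bh_mark(
    results: list[EnrichmentResult],
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> MarkedResults:
    """Fill the significance column by BH step-up at each alpha level.

    Marks are nested: every "**" category is also significant at the looser
    level. p = 0 (possible under the strictly-greater convention) simply
    participates as 0. The input list is modified in place and returned.
    """
    alpha1, alpha2 = alpha_levels
    if not (0 < alpha2 < alpha1 < 1):
        raise ValueError("alpha levels must satisfy 0 < alpha2 < alpha1 < 1")
    tested = [r for r in results if r.empirical_p is not None]
    for r in results:
        r.significance = None if r.empirical_p is None else ""
    if tested:
        pvals = np.array([r.empirical_p for r in tested])
        rej1 = multipletests(pvals, alpha=alpha1, method="fdr_bh")[0]
        rej2 = multipletests(pvals, alpha=alpha2, method="fdr_bh")[0]
        for r, s1, s2 in zip(tested, rej1, rej2):
            r.significance = "**" if s2 else ("*" if s1 else "")
    return MarkedResults(results, m=len(tested))


def hypergeom_pvalue(
    query_targets: TargetBitset, category: CategoryIndex, universe_size: int
) -> float:
    """One-sided over-representation tail P[X >= overlap].

    X ~ Hypergeometric(population=universe_size, successes=category.size,
    draws=|query_targets|); overlap is the observed intersection size.
    """
    draws = query_targets.cardinality()
    if universe_size < draws or category.size > universe_size:
        raise ValueError("hypergeometric parameters inconsistent with the universe")
    cat_bits = TargetBitset.from_positions(category.gene_bits, query_targets.n_bits)
    overlap = popcount_overlap(query_targets, cat_bits)
    # sf(k-1) = P[X >= k]
    return float(hypergeom.sf(overlap - 1, universe_size, category.size, draws))
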