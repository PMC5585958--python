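"""Per-category enrichment result record.

A category with zero overlap with the query group's targets is excluded from
the Monte Carlo test: its ``empirical_p`` is None (printed as ``NA``) and it
never enters the multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class EnrichmentResult:
    """Overlap statistics and empirical p-value for one annotation category.

    Attributes
    ----------
    category_id, category_name
        Identity of the annotation category (e.g. a GO term).
    category_size
        Number of annotated genes retained after gene-universe filtering;
        the denominator of ``overlap_proportion``.
    overlap_count
        ``|query target union ∩ category|`` in genes.
    overlap_proportion
        ``overlap_count / category_size``.
    exceed_count
        Number of random miRNA groups whose overlap with this category
        exceeds the query's (strictly, by default). None for excluded
        categories.
    empirical_p
        ``exceed_count / N`` (or the (k+1)/(N+1) estimator); None when the
        category was excluded for zero overlap.
    significance
        "" / "*" / "**" after Benjamini-Hochberg marking; None for excluded
        categories (printed as ``NA``).
    """

    category_id: str
    category_name: str
    category_size: int
    overlap_count: int
    overlap_proportion: float
    exceed_count: int | None = None
    empirical_p: float | None = None
    significance: str | None = field(default=None)

    @property
    def tested(self) -> bool:
        return self.empirical_p is not None


def sort_key(r: EnrichmentResult):
    """Ascending empirical p, then category id; excluded (NA) rows last."""
    return (r.empirical_p is None, r.empirical_p if r.empirical_p is not None else 0.0, r.category_id)
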