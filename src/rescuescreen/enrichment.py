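"""DAVID-style functional-annotation enrichment.

For a submitted gene list and an annotation catalog (categories of terms,
each term a gene set, over a background universe), every term is scored
with the EASE statistic: a one-tailed Fisher exact upper-tail probability
of the 2x2 list/term table in which the observed list-hit count is
replaced by ``max(count - 1, 0)``. The jackknifed count makes single-gene
overlaps uninformative (p = 1) and is deliberately conservative relative
to the plain Fisher test.

Reported per term, mirroring DAVID's chart columns: member count, percent
of the submitted list, EASE p, list total (list genes carrying any
annotation in the category), fold enrichment
``(count/list_total) / (pop_hits/pop_total)``, and a Benjamini–Hochberg
FDR over the terms tested within the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from scipy.stats import hypergeom

from rescuescreen.differential import bh_adjust


def _check_margins(list_hits: int, list_total: int, pop_hits: int, pop_total: int) -> None:
    if not (0 <= list_hits <= list_total <= pop_total):
        raise ValueError(
            f"inconsistent margins: need 0 <= list_hits <= list_total <= pop_total, "
            f"got ({list_hits}, {list_total}, {pop_hits}, {pop_total})"
        )
    if not (list_hits <= pop_hits <= pop_total):
        raise ValueError(
            f"inconsistent margins: need list_hits <= pop_hits <= pop_total, "
            f"got ({list_hits}, {list_total}, {pop_hits}, {pop_total})"
        )


def ease_p(
    list_hits: int,
    list_total: int,
    pop_hits: int,
    pop_total: int,
    jackknife: bool = True,
) -> float:
    """EASE score of a 2x2 enrichment table.

    The upper-tail hypergeometric probability
    ``P(X >= list_hits)`` with ``X ~ Hypergeom(pop_total, pop_hits,
    list_total)``, computed after replacing ``list_hits`` with
    ``max(list_hits - 1, 0)`` (the EASE jackknife). ``jackknife=False``
    gives the plain one-tailed Fisher exact p.
    """
    _check_margins(list_hits, list_total, pop_hits, pop_total)
    k = max(list_hits - 1, 0) if jackknife else list_hits
    # P(X >= k) = sf(k - 1)
    return float(min(1.0, hypergeom.sf(k - 1, pop_total, pop_hits, list_total)))


def fold_enrichment(list_hits: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """(list_hits/list_total) / (pop_hits/pop_total)."""
    _check_margins(list_hits, list_total, pop_hits, pop_total)
    if list_total == 0 or pop_hits == 0:
        raise ValueError("list_total and pop_hits must be positive")
    return (list_hits / list_total) / (pop_hits / pop_total)


def percent_of_list(count: int, submitted: int) -> float:
    """Percentage of the submitted gene list carrying a term: 100*count/submitted."""
    if submitted <= 0:
        raise ValueError("submitted list size must be positive")
    if not 0 <= count <= submitted:
        raise ValueError(f"count must be in [0, {submitted}], got {count}")
    return 100.0 * count / submitted


@dataclass
class AnnotationCatalog:
    """Category -> term -> gene-set annotation with a background universe.

    Attributes
    ----------
    terms
        Term name -> member gene set.
    categories
        Term name -> category label (e.g. a keyword system or GO branch).
    universe
        Background gene universe; member sets are intersected with it for
        all population margins. Defaults to the union of all members.
    """

    terms: dict[str, frozenset[str]]
    categories: dict[str, str]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        missing = set(self.terms) - set(self.categories)
        if missing:
            raise ValueError(f"terms without a category: {sorted(missing)[:5]}")
        if not self.universe:
            u: set[str] = set()
            for members in self.terms.values():
                u |= members
            self.universe = frozenset(u)

    def category_terms(self, category: str) -> list[str]:
        return sorted(t for t, c in self.categories.items() if c == category)

    def pop_hits(self, term: str) -> int:
        return len(self.terms[term] & self.universe)

    def pop_total(self, category: str) -> int:
        members: set[str] = set()
        for t in self.category_terms(category):
            members |= self.terms[t]
        return len(members & self.universe)


@dataclass
class EnrichmentRow:
    """One chart row: a term's enrichment in the submitted list."""

    category: str
    term: str
    count: int
    percent: float
    ease_p: float
    list_total: int
    pop_hits: int
    pop_total: int
    fold_enrichment: float
    fdr: float
    gene_ids: tuple[str, ...]


def enrich(
    gene_list: Iterable[str],
    catalog: AnnotationCatalog,
    min_count: int = 2,
    submitted: int | None = None,
    jackknife: bool = True,
) -> list[EnrichmentRow]:
    """Score every catalog term against a gene list.

    Parameters
    ----------
    gene_list
        Submitted genes; intersected with the catalog universe before
        testing.
    min_count
        Minimum list-hit count for a term to be reported (default 2).
    submitted
        Denominator of the percent column — the number of submitted genes
        mapped to the catalog. Defaults to the size of the intersection
        with the universe.
    jackknife
        Use the EASE count-minus-one statistic (default) or plain Fisher.

    Returns rows sorted by EASE p ascending, ties broken by term name;
    the FDR column is a BH adjustment over the tested terms within each
    category.
    """
    genes = set(gene_list) & set(catalog.universe)
    if not genes:
        raise ValueError("zero submitted genes map to the catalog universe")
    n_submitted = submitted if submitted is not None else len(genes)
    if n_submitted <= 0:
        raise ValueError("submitted list size must be positive")

    rows: list[EnrichmentRow] = []
    by_category: dict[str, list[EnrichmentRow]] = {}
    for category in sorted(set(catalog.categories.values())):
        pop_total = catalog.pop_total(category)
        annotated: set[str] = set()
        for t in catalog.category_terms(category):
            annotated |= catalog.terms[t] & catalog.universe
        list_total = len(genes & annotated)
        cat_rows: list[EnrichmentRow] = []
        for term in catalog.category_terms(category):
            members = catalog.terms[term] & catalog.universe
            hits = sorted(genes & members)
            if len(hits) < min_count:
                continue
            p = ease_p(len(hits), list_total, len(members), pop_total, jackknife=jackknife)
            cat_rows.append(
                EnrichmentRow(
                    category=category,
                    term=term,
                    count=len(hits),
                    percent=percent_of_list(len(hits), n_submitted),
                    ease_p=p,
                    list_total=list_total,
                    pop_hits=len(members),
                    pop_total=pop_total,
                    fold_enrichment=fold_enrichment(
                        len(hits), list_total, len(members), pop_total
                    ),
                    fdr=1.0,  # filled below
                    gene_ids=tuple(hits),
                )
            )
        if cat_rows:
            fdrs = bh_adjust([r.ease_p for r in cat_rows])
            for r, f in zip(cat_rows, fdrs):
                r.fdr = float(f)
        by_category[category] = cat_rows
        rows.extend(cat_rows)

    rows.sort(key=lambda r: (r.ease_p, r.term))
    return rows
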