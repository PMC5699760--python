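"""Module over-representation tests: one-sided Fisher exact + Bonferroni.

For each (module, gene-set term) pair the 2x2 table over the background
universe is tested for over-representation: the P-value is the hypergeometric
upper tail P(X >= observed overlap). Bonferroni families are all terms tested
for one module within one collection (category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """A named collection (category) of term -> member-gene sets."""

    category: str
    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"term {term!r} has no member genes")


@dataclass
class EnrichmentResult:
    module: str
    category: str
    term: str
    count: int
    module_size: int
    percent: float
    p_value: float
    p_bonferroni: float


def fisher_overrep(module_genes: set, term_genes: set, background: set) -> float:
    """One-sided (over-representation) Fisher exact P for a module/term pair.

    Hypergeometric upper tail of drawing ``len(module_genes)`` genes from the
    background and seeing at least the observed overlap with the term. Term
    genes outside the background are ignored.
    """
    if not background:
        raise ValueError("background universe must be non-empty")
    if not set(module_genes) <= set(background):
        raise ValueError("module genes must be a subset of the background")
    term_in_bg = set(term_genes) & set(background)
    dropped = len(set(term_genes)) - len(term_in_bg)
    if dropped:
        logger.info("ignored %d term gene(s) outside the background", dropped)
    overlap = len(set(module_genes) & term_in_bg)
    n_bg = len(set(background))
    n_term = len(term_in_bg)
    n_module = len(set(module_genes))
    # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=n_term, n=n_module)
    p = float(hypergeom.sf(overlap - 1, n_bg, n_term, n_module))
    return min(1.0, max(0.0, p))


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) with m = family size."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def enrich_modules(
    assignment,
    collections: list[GeneSetCollection],
    background: set,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Test every non-grey module against every term of every collection.

    Grey genes are excluded from modules but remain in the background if
    present there. Terms with fewer than ``min_term_size`` background members
    are skipped as untestable. Rows come back sorted by (module, category,
    raw P ascending, term).
    """
    modules = assignment.modules()
    background = set(background)
    results: list[EnrichmentResult] = []
    for module_name in sorted(modules):
        module_genes = set(modules[module_name]) & background
        if not module_genes:
            continue
        for coll in collections:
            rows: list[EnrichmentResult] = []
            n_skipped = 0
            for term in sorted(coll.sets):
                term_in_bg = coll.sets[term] & background
                if len(term_in_bg) < min_term_size:
                    n_skipped += 1
                    continue
                count = len(module_genes & term_in_bg)
                p = fisher_overrep(module_genes, term_in_bg, background)
                rows.append(
                    EnrichmentResult(
                        module=module_name,
                        category=coll.category,
                        term=term,
                        count=count,
                        module_size=len(module_genes),
                        percent=100.0 * count / len(module_genes),
                        p_value=p,
                        p_bonferroni=p,  # adjusted below once the family is known
                    )
                )
            if n_skipped:
                logger.info(
                    "module %s, category %s: skipped %d term(s) with < %d background members",
                    module_name,
                    coll.category,
                    n_skipped,
                    min_term_size,
                )
            adjusted = bonferroni([r.p_value for r in rows])
            for r, padj in zip(rows, adjusted):
                r.p_bonferroni = padj
            results.extend(rows)
    results.sort(key=lambda r: (r.module, r.category, r.p_value, r.term))
    return results
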