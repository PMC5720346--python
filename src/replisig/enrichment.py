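"""Per-term Fisher's exact gene-set enrichment with Bonferroni control.

Each term is tested independently with the one-sided hypergeometric upper
tail (enrichment only); results report the classic Annotated / Found /
Expected columns: Annotated = |set ∩ universe|, Found = |set ∩ query|,
Expected = Annotated * |query| / |universe|. The universe is caller-supplied
(the genes measured on the platform), never hard-coded. Multiplicity is
controlled by a flat Bonferroni threshold alpha / n_terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "load_gene_sets",
    "fisher_enrichment",
    "bonferroni_threshold",
]


@dataclass
class GeneSetCollection:
    """Gene sets restricted to a measurement universe."""

    sets: dict[str, frozenset]     # term id -> member gene ids
    names: dict[str, str]          # term id -> human-readable name
    universe: frozenset

    @property
    def n_terms(self) -> int:
        return len(self.sets)


def load_gene_sets(gmt_path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file (term, description, members...) restricted to a universe.

    Duplicate members within a line are counted once; sets empty after
    restriction to the universe are dropped with a warning. A line with
    fewer than three tab-separated fields is a parse error.
    """
    universe = frozenset(universe)
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    path = Path(gmt_path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        term, desc, members = fields[0], fields[1], fields[2:]
        if term in sets:
            raise ValidationError(f"{path}:{lineno}: duplicated term id {term!r}")
        restricted = frozenset(members) & universe
        if not restricted:
            logger.warning("term %s has no members in the universe; dropped", term)
            continue
        sets[term] = restricted
        names[term] = desc
    return GeneSetCollection(sets=sets, names=names, universe=universe)


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of a query list in every term.

    Returns one row per term ranked by p-value with columns ``term``,
    ``name``, ``annotated``, ``found``, ``expected``, ``pvalue``,
    ``depleted`` (flagged, never tested) and ``bonferroni_significant``.
    Query genes outside the universe are trimmed with a logged warning.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.warning("%d query genes outside the universe trimmed", len(outside))
        query -= outside
    if not query:
        raise ValidationError("query is empty after restriction to the universe")
    n_universe = len(collection.universe)
    n_query = len(query)
    threshold = bonferroni_threshold(alpha, collection.n_terms)
    rows = []
    for term, members in collection.sets.items():
        annotated = len(members)
        found = len(members & query)
        expected = annotated * n_query / n_universe
        # upper tail: P(X >= found) for X ~ Hypergeom(N, annotated, n_query)
        pvalue = float(stats.hypergeom.sf(found - 1, n_universe, annotated, n_query))
        pvalue = min(max(pvalue, 5e-324), 1.0)
        rows.append(
            {
                "term": term,
                "name": collection.names[term],
                "annotated": annotated,
                "found": found,
                "expected": expected,
                "pvalue": pvalue,
                "depleted": found < expected,
                "bonferroni_significant": pvalue <= threshold,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["pvalue", "term"], kind="mergesort", ignore_index=True
    )
    return out


def bonferroni_threshold(alpha: float, n_terms: int) -> float:
    """Flat per-test threshold alpha / n_terms."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if n_terms < 1:
        raise ValidationError("n_terms must be at least 1")
    return alpha / n_terms
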