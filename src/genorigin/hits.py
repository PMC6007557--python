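"""Hit-quality filtering, self-hit removal, and top-N selection.

Two filter presets are used throughout:

* strict — an HSP is kept iff it covers >= 90% of the query protein AND has
  amino-acid similarity >= 40%; this is the filter behind the four-way
  origin classification (what it *removes* is coverage < 0.90 or
  similarity < 40, so exact-threshold hits survive).
* relaxed — coverage >= 80% and similarity >= 30%; used only to gather more
  distant homologs when selecting gene-tree candidates.

Filters apply per HSP; a subject qualifies if any of its HSPs passes, and
its representative row is its best-bit-score passing HSP.  Ranking of
subjects is by descending bit score with ties broken by ascending
subject_id so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import Hit, TaxonomyMap

_STRICT = (0.90, 40.0)
_RELAXED = (0.80, 30.0)


@dataclass(frozen=True)
class FilterPolicy:
    """Minimum query coverage (fraction) and percent similarity for a hit."""

    min_coverage: float
    min_similarity: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode == "strict" and (self.min_coverage, self.min_similarity) != _STRICT:
            raise ValueError("strict preset thresholds are fixed at (0.90, 40)")
        if self.mode == "relaxed" and (self.min_coverage, self.min_similarity) != _RELAXED:
            raise ValueError("relaxed preset thresholds are fixed at (0.80, 30)")
        if self.mode not in ("strict", "relaxed", "custom"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    @classmethod
    def strict(cls) -> "FilterPolicy":
        return cls(*_STRICT, mode="strict")

    @classmethod
    def relaxed(cls) -> "FilterPolicy":
        return cls(*_RELAXED, mode="relaxed")

    @classmethod
    def custom(cls, min_coverage: float, min_similarity: float) -> "FilterPolicy":
        return cls(min_coverage, min_similarity, mode="custom")

    def passes(self, hit: Hit) -> bool:
        return (
            hit.coverage >= self.min_coverage
            and hit.percent_similarity >= self.min_similarity
        )


def remove_self_hits(hits: Sequence[Hit], taxonomy: TaxonomyMap) -> list[Hit]:
    """Drop hits to the focal genome itself; input order is preserved.

    A hit is a self-hit if its subject taxon is the focal taxon, or if its
    subject id equals its own query id (same protein deposited elsewhere).
    """
    return [
        h
        for h in hits
        if h.subject_taxon != taxonomy.focal_taxon and h.subject_id != h.query_id
    ]


def filter_hits(hits: Sequence[Hit], policy: FilterPolicy) -> list[Hit]:
    """Keep hits meeting both thresholds (boundary inclusive); order preserved."""
    return [h for h in hits if policy.passes(h)]


def top_hits(hits: Sequence[Hit], n: int) -> list[Hit]:
    """Collect up to ``n`` top subjects per query.

    HSPs are grouped by subject, each subject represented by its best-scoring
    HSP; subjects are ranked by descending bit score, ties by ascending
    subject_id.  Output is grouped by query in lexicographic query order, so
    the result is independent of input row order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best: dict[str, dict[str, Hit]] = {}
    for h in hits:
        per_query = best.setdefault(h.query_id, {})
        cur = per_query.get(h.subject_id)
        # deterministic representative under any input order: best score,
        # then higher similarity, then leftmost alignment
        if cur is None or _hsp_rank(h) > _hsp_rank(cur):
            per_query[h.subject_id] = h
    out: list[Hit] = []
    for q in sorted(best):
        reps = sorted(best[q].values(), key=lambda h: (-h.bit_score, h.subject_id))
        out.extend(reps[:n])
    return out


def _hsp_rank(h):
    return (h.bit_score, h.percent_similarity, -h.align_q_start, -h.align_q_end)


def top_hits_by_query(hits: Sequence[Hit], n: int) -> dict[str, list[Hit]]:
    """Like :func:`top_hits` but returning the per-query ranked lists."""
    ranked = top_hits(hits, n)
    out: dict[str, list[Hit]] = {}
    for h in ranked:
        out.setdefault(h.query_id, []).append(h)
    return out
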