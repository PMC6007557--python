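"""Four-way gene-origin classification and donor-clade assignment.

The verdict for a gene depends only on the taxonomic composition of its
filtered top-5 hit list:

* empty list                       -> ``species_specific`` (orphan)
* all hits in the focal clade      -> ``native``
* no hit in the focal clade        -> ``hgt_high``
* mixture                          -> ``hgt_low``

High-confidence acquired genes get a donor clade by plurality vote over
their evidence hits (ties broken by larger summed bit score, then
lexicographic clade label).  Low-confidence candidates get the same vote
over their non-focal hits, flagged tentative; downstream island detection
uses high-confidence calls only.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .hits import FilterPolicy, filter_hits, remove_self_hits, top_hits_by_query
from .model import ContractError, Gene, Hit, LoadError, OriginCall, TaxonomyMap


def classify_gene(
    gene_id: str, top5: Sequence[Hit], taxonomy: TaxonomyMap
) -> OriginCall:
    """Classify one gene from its filtered, ranked top-5 hit list."""
    n_focal = 0
    n_nonfocal = 0
    for h in top5:
        if taxonomy.is_focal(h.subject_taxon):  # raises LoadError on unknown taxon
            n_focal += 1
        else:
            n_nonfocal += 1
    if not top5:
        origin = "species_specific"
    elif n_nonfocal == 0:
        origin = "native"
    elif n_focal == 0:
        origin = "hgt_high"
    else:
        origin = "hgt_low"
    call = OriginCall(
        gene_id=gene_id,
        origin_class=origin,
        n_focal_hits=n_focal,
        n_nonfocal_hits=n_nonfocal,
        evidence=tuple(top5),
        top_subjects=tuple(h.subject_id for h in top5),
    )
    if origin == "hgt_high":
        call.donor_clade = _donor_vote(top5, taxonomy)
    elif origin == "hgt_low":
        call.donor_clade = _donor_vote(
            [h for h in top5 if not taxonomy.is_focal(h.subject_taxon)], taxonomy
        )
        call.donor_tentative = True
    return call


def _donor_vote(evidence: Sequence[Hit], taxonomy: TaxonomyMap) -> str:
    """Plurality clade; ties by larger summed bit score, then clade label."""
    count: dict[str, int] = {}
    score: dict[str, float] = {}
    for h in evidence:
        clade = taxonomy.clade_of(h.subject_taxon)
        count[clade] = count.get(clade, 0) + 1
        score[clade] = score.get(clade, 0.0) + h.bit_score
    return min(count, key=lambda c: (-count[c], -score[c], c))


def assign_donor(call: OriginCall, taxonomy: TaxonomyMap) -> str:
    """Donor clade of a high-confidence acquired gene."""
    if call.origin_class != "hgt_high":
        raise ContractError(
            f"assign_donor called on {call.origin_class!r} gene {call.gene_id!r}"
        )
    if not call.evidence:
        raise ContractError(f"gene {call.gene_id!r} has no evidence hits")
    return _donor_vote(call.evidence, taxonomy)


def classify_genome(
    genes: Sequence[Gene],
    hits: Sequence[Hit],
    taxonomy: TaxonomyMap,
    policy: Optional[FilterPolicy] = None,
    n_top: int = 5,
    absent_means_no_hits: bool = False,
) -> list[OriginCall]:
    """Classify every gene; returns one call per gene in chromosome order.

    The fixed pipeline is self-hit removal, then quality filtering, then
    top-N selection, then the four-way verdict.  A gene entirely absent from
    the raw hit table is an input-completeness error unless
    ``absent_means_no_hits`` is set (in which case it is an orphan).
    """
    policy = policy or FilterPolicy.strict()
    present = {h.query_id for h in hits}
    if not absent_means_no_hits:
        missing = [g.gene_id for g in genes if g.gene_id not in present]
        if missing:
            raise LoadError(
                f"{len(missing)} gene(s) absent from the hit table "
                f"(first: {missing[0]!r}); pass absent_means_no_hits=True if the "
                "table is known to omit no-hit queries"
            )
    clean = filter_hits(remove_self_hits(hits, taxonomy), policy)
    per_query = top_hits_by_query(clean, n_top)
    return [classify_gene(g.gene_id, per_query.get(g.gene_id, []), taxonomy) for g in genes]


def class_counts(calls: Sequence[OriginCall]) -> dict[str, int]:
    out = {c: 0 for c in ("native", "species_specific", "hgt_low", "hgt_high")}
    for call in calls:
        out[call.origin_class] += 1
    return out


def select_tree_candidates(
    calls: Sequence[OriginCall],
    hits: Sequence[Hit],
    taxonomy: TaxonomyMap,
    min_focal_homologs: int = 5,
    top_n: int = 100,
    policy: Optional[FilterPolicy] = None,
) -> list[str]:
    """Select acquired genes suitable for individual gene-tree analysis.

    A high-confidence acquired gene qualifies if its relaxed-filter top-100
    hit list contains at least ``min_focal_homologs`` hits from focal-clade
    species other than the focal genome itself.
    """
    policy = policy or FilterPolicy.relaxed()
    clean = filter_hits(remove_self_hits(hits, taxonomy), policy)
    per_query = top_hits_by_query(clean, top_n)
    selected: list[str] = []
    for call in calls:
        if call.origin_class != "hgt_high":
            continue
        n_focal = sum(
            1
            for h in per_query.get(call.gene_id, [])
            if taxonomy.is_focal(h.subject_taxon)
        )
        if n_focal >= min_focal_homologs:
            selected.append(call.gene_id)
    return selected
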