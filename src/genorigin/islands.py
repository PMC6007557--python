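"""Detection of acquired islands on a circular chromosome.

An acquired island is a maximal run of high-confidence acquired genes that
share a donor clade.  Contiguity is defined at the gene level: two
same-donor acquired genes belong to the same run if at most ``max_gap``
genes of any other class or donor lie between them (the chromosome being
circular, runs may cross the replication origin).  Runs with at least
``min_genes`` members are reported as islands.

An optional synteny screen checks whether the island members' best-hit
subjects, taken in chromosome order, appear as an ordered common
subsequence (forward or reverse, i.e. inversions allowed) of a donor
genome's gene order.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .model import ContractError, Gene, Island, OriginCall


def detect_islands(
    calls: Sequence[OriginCall],
    genes: Sequence[Gene],
    min_genes: int = 5,
    max_gap: int = 2,
    circular: bool = True,
) -> list[Island]:
    """Find maximal same-donor runs of high-confidence acquired genes.

    ``calls`` and ``genes`` must be parallel lists in chromosome order.
    Islands are returned sorted by span start; each gene belongs to at most
    one island.
    """
    if len(calls) != len(genes):
        raise ContractError("calls/genes length mismatch")
    for c, g in zip(calls, genes):
        if c.gene_id != g.gene_id:
            raise ContractError(
                f"calls/genes out of register at {c.gene_id!r} vs {g.gene_id!r}"
            )
    n = len(calls)
    by_donor: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        if c.origin_class == "hgt_high":
            if c.donor_clade is None:
                raise ContractError(f"hgt_high gene {c.gene_id!r} lacks a donor clade")
            by_donor.setdefault(c.donor_clade, []).append(i)

    islands: list[Island] = []
    for donor in sorted(by_donor):
        for run in _runs(by_donor[donor], n, max_gap, circular):
            if len(run) < min_genes:
                continue
            first, last = run[0], run[-1]
            interval = (last - first) % n + 1 if circular else last - first + 1
            islands.append(
                Island(
                    island_id="",  # numbered after global sort below
                    donor_clade=donor,
                    gene_ids=tuple(genes[i].gene_id for i in run),
                    span_start=genes[first].start,
                    span_end=genes[last].end,
                    n_acquired=len(run),
                    n_interrupting=interval - len(run),
                    best_hit_subjects=tuple(
                        calls[i].top_subjects[0] if calls[i].top_subjects else ""
                        for i in run
                    ),
                )
            )
    islands.sort(key=lambda isl: (isl.span_start, isl.donor_clade))
    for k, isl in enumerate(islands, start=1):
        isl.island_id = f"island_{k}"
    return islands


def _runs(idx: list[int], n: int, max_gap: int, circular: bool) -> list[list[int]]:
    """Chain sorted member indices into maximal runs under the gap rule."""
    m = len(idx)
    if m == 0:
        return []
    if m == 1:
        return [[idx[0]]]
    runs: list[list[int]] = [[idx[0]]]
    for k in range(1, m):
        if idx[k] - idx[k - 1] - 1 <= max_gap:
            runs[-1].append(idx[k])
        else:
            runs.append([idx[k]])
    if circular and (idx[0] - idx[-1] - 1) % n <= max_gap:
        if len(runs) > 1:
            # bridge the origin: last run continues into the first
            runs[0] = runs.pop() + runs[0]
        else:
            # every member chains around the full circle; pick a canonical
            # start just after the widest inter-member gap
            gaps = [(idx[(k + 1) % m] - idx[k] - 1) % n for k in range(m)]
            kmax = max(range(m), key=lambda k: (gaps[k], -k))
            runs = [[idx[(kmax + 1 + j) % m] for j in range(m)]]
    return runs


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest common subsequence length (classic DP)."""
    la, lb = len(a), len(b)
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[lb]


def check_synteny(
    island: Island,
    donor_order: Optional[Sequence[str]],
    min_genes: int = 5,
) -> Optional[bool]:
    """Screen an island for conserved gene order against a donor genome.

    ``donor_order`` lists a donor genome's proteins (subject ids) in
    chromosome order.  The island passes if its members' best-hit subjects,
    in chromosome order, share an ordered common subsequence of length
    >= ``min_genes`` with ``donor_order`` read forward or in reverse.
    Returns None (and leaves the island unchecked) when no donor order is
    supplied.
    """
    if donor_order is None:
        island.synteny_checked = False
        island.synteny_pass = None
        return None
    members = [s for s in island.best_hit_subjects if s]
    fwd = _lcs_len(members, list(donor_order))
    rev = _lcs_len(members, list(reversed(donor_order)))
    island.synteny_checked = True
    island.synteny_pass = max(fwd, rev) >= min_genes
    return island.synteny_pass
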