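"""Genome-level summary statistics.

Covers the per-class gene-count and chromosome-length fractions, windowed
GC content and GC skew tracks for circular-plot rendering, the discrepancy
between an assembled genome size and a PFGE estimate, unweighted
cross-species class-percentage averages, and donor/COG breakdowns of the
high-confidence acquired genes.

All printed-style percentages are integers rounded half-up, matching the
convention of published gene-count tables.  Length fractions divide the
summed nucleotide spans of a class's genes by the chromosome length;
intergenic DNA belongs to no class, so the four length percentages sum
below 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ContractError, Gene, LoadError, OriginCall

CLASS_ORDER = ("native", "species_specific", "hgt_low", "hgt_high")


def round_half_up(x) -> int:
    """Round to the nearest integer with exact halves rounding up."""
    if isinstance(x, Fraction):
        return math.floor(x + Fraction(1, 2))
    return math.floor(Fraction(str(float(x))) + Fraction(1, 2))


def pct_int(count: int, total: int) -> int:
    """Integer percentage of count/total, half-up, computed exactly."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(Fraction(100 * count, total))


@dataclass
class TrackPoint:
    """One sliding-window value on the chromosome (window_start is 1-based)."""

    window_start: int
    value: Optional[float]
    degenerate: bool = False


@dataclass
class GenomeSummary:
    total_genes: int = 0
    class_counts: dict = field(default_factory=dict)
    class_count_pct: dict = field(default_factory=dict)
    class_span_bp: dict = field(default_factory=dict)
    class_length_pct: dict = field(default_factory=dict)
    donor_breakdown: dict = field(default_factory=dict)
    cog_breakdown: dict = field(default_factory=dict)
    assembled_size_bp: Optional[int] = None
    pfge_size_bp: Optional[int] = None
    pfge_discrepancy_pct: Optional[int] = None
    mean_gc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "class_counts": self.class_counts,
            "class_count_pct": self.class_count_pct,
            "class_span_bp": self.class_span_bp,
            "class_length_pct": self.class_length_pct,
            "donor_breakdown": self.donor_breakdown,
            "cog_breakdown": self.cog_breakdown,
            "assembled_size_bp": self.assembled_size_bp,
            "pfge_size_bp": self.pfge_size_bp,
            "pfge_discrepancy_pct": self.pfge_discrepancy_pct,
            "mean_gc": self.mean_gc,
        }


def class_fractions(
    calls: Sequence[OriginCall], genes: Sequence[Gene], chrom_len: int
) -> GenomeSummary:
    """Per-class counts, integer count-percentages, and length fractions."""
    if len(calls) != len(genes):
        raise ContractError("calls/genes length mismatch")
    max_coord = max((max(g.start, g.end) for g in genes), default=0)
    if chrom_len < max_coord:
        raise LoadError(
            f"chromosome length {chrom_len} smaller than max gene coordinate {max_coord}"
        )
    counts = {c: 0 for c in CLASS_ORDER}
    spans = {c: 0 for c in CLASS_ORDER}
    for call, gene in zip(calls, genes):
        counts[call.origin_class] += 1
        spans[call.origin_class] += gene.span_bp(chrom_len)
    total = len(calls)
    summary = GenomeSummary(
        total_genes=total,
        class_counts=counts,
        class_count_pct={c: pct_int(counts[c], total) for c in CLASS_ORDER}
        if total
        else {c: 0 for c in CLASS_ORDER},
        class_span_bp=spans,
        class_length_pct={c: pct_int(spans[c], chrom_len) for c in CLASS_ORDER},
        assembled_size_bp=chrom_len,
    )
    return summary


def _base_arrays(sequence: str):
    b = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_g = (b == ord("G")).astype(np.int64)
    is_c = (b == ord("C")).astype(np.int64)
    is_at = ((b == ord("A")) | (b == ord("T"))).astype(np.int64)
    return is_g, is_c, is_at


def _window_sums(x: np.ndarray, window: int, starts: np.ndarray) -> np.ndarray:
    ext = np.concatenate([x, x[: window - 1]]) if window > 1 else x
    cum = np.concatenate([[0], np.cumsum(ext)])
    return cum[starts + window] - cum[starts]


def _window_starts(length: int, window: int, step: int, circular: bool) -> np.ndarray:
    if window > length:
        raise ValueError(f"window {window} exceeds sequence length {length}")
    if circular:
        return np.arange(0, length, step)
    return np.arange(0, length - window + 1, step)


def gc_content_track(
    sequence: str, window: int = 10_000, step: int = 1_000, circular: bool = True
) -> tuple[list[TrackPoint], float]:
    """Windowed GC content plus the genome-wide mean.

    The denominator counts unambiguous bases only; an all-N window is
    emitted as a missing point.  Windows wrap the origin on circular
    replicons.
    """
    is_g, is_c, is_at = _base_arrays(sequence)
    starts = _window_starts(len(sequence), window, step, circular)
    gc = _window_sums(is_g + is_c, window, starts)
    acgt = gc + _window_sums(is_at, window, starts)
    points = []
    for s, g, d in zip(starts, gc, acgt):
        if d == 0:
            points.append(TrackPoint(int(s) + 1, None, degenerate=True))
        else:
            points.append(TrackPoint(int(s) + 1, float(g) / float(d)))
    total_gc = int((is_g + is_c).sum())
    total_acgt = total_gc + int(is_at.sum())
    if total_acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return points, total_gc / total_acgt


def gc_skew_track(
    sequence: str, window: int = 10_000, step: int = 1_000, circular: bool = True
) -> list[TrackPoint]:
    """Windowed GC skew, (G - C) / (G + C); a G+C-free window yields 0 (flagged)."""
    is_g, is_c, _ = _base_arrays(sequence)
    starts = _window_starts(len(sequence), window, step, circular)
    g = _window_sums(is_g, window, starts)
    c = _window_sums(is_c, window, starts)
    points = []
    for s, gi, ci in zip(starts, g, c):
        denom = gi + ci
        if denom == 0:
            points.append(TrackPoint(int(s) + 1, 0.0, degenerate=True))
        else:
            points.append(TrackPoint(int(s) + 1, float(gi - ci) / float(denom)))
    return points


def pfge_discrepancy(assembled_bp: int, pfge_bp: int) -> int:
    """Percent by which a PFGE size estimate exceeds the assembled size."""
    if assembled_bp <= 0 or pfge_bp <= 0:
        raise ValueError("genome sizes must be positive")
    return round_half_up(Fraction(100 * (pfge_bp - assembled_bp), pfge_bp))


def cross_species_average(
    table: pd.DataFrame, origin_class: str, exclude: Sequence[str] = ()
) -> int:
    """Unweighted mean class percentage over the included species rows.

    ``table`` is indexed by species with one integer column per origin
    class.  Each row's class percentage uses that row's four-class total as
    denominator; the mean over species is then rounded half-up.
    """
    if origin_class not in CLASS_ORDER:
        raise ValueError(f"unknown origin class {origin_class!r}")
    rows = table.loc[[s for s in table.index if s not in set(exclude)]]
    if rows.empty:
        raise ValueError("no species left after exclusion")
    pcts = []
    for _, row in rows.iterrows():
        total = int(sum(row[c] for c in CLASS_ORDER))
        pcts.append(Fraction(100 * int(row[origin_class]), total))
    return round_half_up(sum(pcts) / len(pcts))


def breakdowns(
    calls: Sequence[OriginCall], genes: Sequence[Gene]
) -> tuple[dict[str, float], dict[str, float]]:
    """Donor-clade and COG-category fractions over high-confidence acquired genes.

    Genes without a COG letter are pooled under ``unassigned``.  With zero
    acquired genes both breakdowns are empty.
    """
    cog_by_id = {g.gene_id: g.cog for g in genes}
    acquired = [c for c in calls if c.origin_class == "hgt_high"]
    if not acquired:
        return {}, {}
    n = len(acquired)
    donor: dict[str, int] = {}
    cog: dict[str, int] = {}
    for c in acquired:
        donor[c.donor_clade or "unassigned"] = donor.get(c.donor_clade or "unassigned", 0) + 1
        letter = cog_by_id.get(c.gene_id) or "unassigned"
        cog[letter] = cog.get(letter, 0) + 1
    return (
        {k: v / n for k, v in sorted(donor.items())},
        {k: v / n for k, v in sorted(cog.items())},
    )


def load_species_counts(path: Optional[str] = None) -> pd.DataFrame:
    """Load a per-species class-count table (defaults to the packaged one).

    The packaged table holds published gene-origin counts for sequenced
    Apis-clade Spiroplasma genomes; the ``reference_only`` column marks rows
    excluded from cross-species averages (the divergent outgroup species for
    which best-hit classification is not applicable).
    """
    if path is None:
        ref = resources.files("genorigin.data").joinpath("apis_clade_gene_origin_counts.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("species")


def build_summary(
    calls: Sequence[OriginCall],
    genes: Sequence[Gene],
    chrom_len: int,
    pfge_bp: Optional[int] = None,
    mean_gc: Optional[float] = None,
) -> GenomeSummary:
    """Assemble the full summary: fractions, breakdowns, and size comparison."""
    summary = class_fractions(calls, genes, chrom_len)
    summary.donor_breakdown, summary.cog_breakdown = breakdowns(calls, genes)
    summary.mean_gc = mean_gc
    if pfge_bp is not None:
        summary.pfge_size_bp = pfge_bp
        summary.pfge_discrepancy_pct = pfge_discrepancy(chrom_len, pfge_bp)
    return summary
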