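"""Shared data model for gene-origin inference on small circular genomes.

The pipeline classifies every protein-coding gene of a focal genome into one
of four evolutionary-origin classes from the taxonomic distribution of its
filtered homology hits:

``native``
    every filtered top hit comes from the focal clade — vertical inheritance
    (or at least no recent transfer from outside the clade).
``species_specific``
    no homolog survives the quality filter at all (orphan gene).
``hgt_low``
    the top hits mix focal-clade and more divergent species — low-confidence
    horizontal-transfer candidate.
``hgt_high``
    no focal-clade species among the top hits — high-confidence candidate of
    horizontal acquisition from a donor clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ORIGIN_CLASSES = ("native", "species_specific", "hgt_low", "hgt_high")


class LoadError(ValueError):
    """Raised when an input file violates the data model at load time."""


class ParseError(ValueError):
    """Raised on a malformed record; carries the offending line number."""


class ConfigError(ValueError):
    """Raised on an invalid or infeasible configuration."""


class ContractError(RuntimeError):
    """Raised when an operation is called outside its contract."""


@dataclass(frozen=True)
class Gene:
    """One annotated protein-coding feature on a circular chromosome.

    Coordinates are 1-based inclusive. A gene wrapping the replication
    origin of a circular chromosome has ``end < start``; its span is then
    computed modularly.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    length_aa: int
    product: str = ""
    cog: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise LoadError(f"gene {self.gene_id!r}: length_aa must be positive")
        if self.start < 1 or self.end < 1:
            raise LoadError(f"gene {self.gene_id!r}: coordinates must be >= 1")
        if self.strand not in ("+", "-"):
            raise LoadError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def span_bp(self, chrom_len: Optional[int] = None) -> int:
        """Nucleotide span of the gene; origin-wrapping spans need chrom_len."""
        if not self.wraps_origin:
            return self.end - self.start + 1
        if chrom_len is None:
            raise ContractError(
                f"gene {self.gene_id!r} wraps the origin; chromosome length required"
            )
        return (chrom_len - self.start + 1) + self.end


@dataclass(frozen=True)
class Hit:
    """One homology hit (HSP) linking a query gene to a subject protein.

    ``coverage`` is the fraction of the query protein covered by the aligned
    segment, ``(align_q_end - align_q_start + 1) / length_aa``; it is derived
    at load time from the query gene's protein length.
    """

    query_id: str
    subject_id: str
    subject_taxon: str
    percent_similarity: float
    align_q_start: int
    align_q_end: int
    bit_score: float
    coverage: float

    def __post_init__(self) -> None:
        if not (1 <= self.align_q_start <= self.align_q_end):
            raise LoadError(
                f"hit {self.query_id!r}->{self.subject_id!r}: bad alignment span"
            )
        if not (0.0 <= self.percent_similarity <= 100.0):
            raise LoadError(
                f"hit {self.query_id!r}->{self.subject_id!r}: similarity outside [0,100]"
            )
        if not (0.0 < self.coverage <= 1.0 + 1e-12):
            raise LoadError(
                f"hit {self.query_id!r}->{self.subject_id!r}: coverage outside (0,1]"
            )
        if self.bit_score < 0:
            raise LoadError(
                f"hit {self.query_id!r}->{self.subject_id!r}: negative bit score"
            )

    @property
    def hit_id(self) -> str:
        """Stable identifier used to reference single hits (e.g. in truth files)."""
        return f"{self.query_id}:{self.subject_id}"


def make_hit(
    query_id: str,
    subject_id: str,
    subject_taxon: str,
    percent_similarity: float,
    align_q_start: int,
    align_q_end: int,
    bit_score: float,
    length_aa: int,
) -> Hit:
    """Construct a Hit, deriving coverage from the query protein length."""
    if align_q_end > length_aa:
        raise LoadError(
            f"hit {query_id!r}->{subject_id!r}: alignment end {align_q_end} "
            f"exceeds query length {length_aa}"
        )
    cov = (align_q_end - align_q_start + 1) / length_aa
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        subject_taxon=subject_taxon,
        percent_similarity=percent_similarity,
        align_q_start=align_q_start,
        align_q_end=align_q_end,
        bit_score=bit_score,
        coverage=cov,
    )


@dataclass
class TaxonomyMap:
    """Maps subject taxa to clade labels and names the focal clade/species."""

    entries: dict[str, str]
    focal_clade: str
    focal_taxon: str

    def __post_init__(self) -> None:
        if self.entries.get(self.focal_taxon) != self.focal_clade:
            raise LoadError(
                f"focal taxon {self.focal_taxon!r} does not map to focal clade "
                f"{self.focal_clade!r}"
            )

    def clade_of(self, taxon: str) -> str:
        try:
            return self.entries[taxon]
        except KeyError:
            raise LoadError(f"unresolvable taxon {taxon!r}") from None

    def is_focal(self, taxon: str) -> bool:
        return self.clade_of(taxon) == self.focal_clade

    @property
    def clades(self) -> set[str]:
        return set(self.entries.values())


@dataclass
class Chromosome:
    """A (usually circular) replicon; sequence is optional."""

    name: str
    length_bp: int
    sequence: Optional[str] = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise LoadError(f"chromosome {self.name!r}: nonpositive length")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise LoadError(
                f"chromosome {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length_bp}"
            )


@dataclass
class OriginCall:
    """Per-gene verdict: origin class, donor clade, and the evidence used."""

    gene_id: str
    origin_class: str
    donor_clade: Optional[str] = None
    donor_tentative: bool = False
    n_focal_hits: int = 0
    n_nonfocal_hits: int = 0
    evidence: tuple = ()
    top_subjects: tuple = ()

    def __post_init__(self) -> None:
        if self.origin_class not in ORIGIN_CLASSES:
            raise ContractError(f"unknown origin class {self.origin_class!r}")


@dataclass
class Island:
    """A maximal run of same-donor, high-confidence acquired genes."""

    island_id: str
    donor_clade: str
    gene_ids: tuple
    span_start: int
    span_end: int
    n_acquired: int
    n_interrupting: int
    best_hit_subjects: tuple = ()
    synteny_checked: bool = False
    synteny_pass: Optional[bool] = None

    @property
    def wraps_origin(self) -> bool:
        return self.span_end < self.span_start
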