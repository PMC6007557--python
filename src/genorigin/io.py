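"""Readers and writers for the external formats the pipeline touches.

Formats:

* gene table — either a narrow GFF3 subset (CDS features only, ``ID`` and
  optional ``product``/``cog``/``length_aa`` attributes, chromosome length
  from the ``##sequence-region`` pragma) or a TSV with sidecar header
  comments (``# chromosome=``, ``# length_bp=``, ``# circular=``).
  Origin-wrapping genes (end < start on a circular replicon) are permitted
  in both dialects, which is why the GFF3 reader is a purpose-built subset
  parser rather than a generic library.
* hit table — tab-separated, one HSP per row, fixed column order
  ``query_id subject_id subject_taxon percent_similarity align_q_start
  align_q_end bit_score`` (extra columns ignored, ``#`` comments and an
  optional header row allowed).  Coverage is derived from the query gene's
  protein length at load time.
* taxonomy — TSV ``taxon<TAB>clade`` with ``# focal_clade=`` and
  ``# focal_taxon=`` header comments.
* chromosome sequence — FASTA over {A,C,G,T,N} (via Biopython).
* outputs — per-gene calls TSV, islands BED (0-based half-open;
  origin-wrapping islands split into two lines sharing a name), summary
  JSON.  All writes are atomic (temp file then rename).

Coordinates are 1-based inclusive everywhere internally; only BED output
uses 0-based half-open.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .model import (
    Chromosome,
    Gene,
    Hit,
    Island,
    LoadError,
    OriginCall,
    ParseError,
    TaxonomyMap,
    make_hit,
)

GENE_TSV_COLUMNS = ["gene_id", "start", "end", "strand", "length_aa", "product", "cog"]
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "subject_taxon",
    "percent_similarity",
    "align_q_start",
    "align_q_end",
    "bit_score",
]
CALL_COLUMNS = [
    "gene_id",
    "origin_class",
    "donor_clade",
    "donor_tentative",
    "n_focal",
    "n_nonfocal",
    "top5_subjects",
]


def _read_sidecar(lines: list[str]) -> dict[str, str]:
    """Collect '# key=value' sidecar comments from the top of a TSV file."""
    meta: dict[str, str] = {}
    for ln in lines:
        if not ln.startswith("#"):
            break
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def _check_gene_coords(gene: Gene, chrom: Chromosome) -> None:
    if gene.start > chrom.length_bp or gene.end > chrom.length_bp:
        raise LoadError(
            f"gene {gene.gene_id!r}: coordinate outside [1, {chrom.length_bp}]"
        )
    if gene.wraps_origin and not chrom.circular:
        raise LoadError(
            f"gene {gene.gene_id!r}: end < start on a non-circular chromosome"
        )


def _sort_genes(genes: list[Gene]) -> list[Gene]:
    return sorted(genes, key=lambda g: (g.start, g.gene_id))


def read_gene_table(path: str, dialect: str = "tsv") -> tuple[list[Gene], Chromosome]:
    """Read an ordered gene list plus chromosome metadata.

    Returns genes sorted by start coordinate.
    """
    if dialect not in ("tsv", "gff3"):
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        return _read_gene_tsv(lines, path)
    return _read_gene_gff3(lines, path)


def _read_gene_tsv(lines: list[str], path: str) -> tuple[list[Gene], Chromosome]:
    meta = _read_sidecar(lines)
    if "length_bp" not in meta:
        raise LoadError(f"{path}: missing '# length_bp=' sidecar field")
    chrom = Chromosome(
        name=meta.get("chromosome", "chr"),
        length_bp=int(meta["length_bp"]),
        circular=meta.get("circular", "true").lower() in ("true", "1", "yes"),
    )
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    if not rows:
        return [], chrom
    header = rows[0].split("\t")
    if header[: len(GENE_TSV_COLUMNS) - 2] != GENE_TSV_COLUMNS[:-2]:
        raise LoadError(f"{path}: unexpected gene-table header {header!r}")
    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        f = row.split("\t")
        try:
            gene = Gene(
                gene_id=f[0],
                start=int(f[1]),
                end=int(f[2]),
                strand=f[3],
                length_aa=int(f[4]),
                product=f[5] if len(f) > 5 else "",
                cog=(f[6] or None) if len(f) > 6 else None,
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if gene.gene_id in seen:
            raise LoadError(f"{path}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        _check_gene_coords(gene, chrom)
        genes.append(gene)
    return _sort_genes(genes), chrom


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gene_gff3(lines: list[str], path: str) -> tuple[list[Gene], Chromosome]:
    chrom: Optional[Chromosome] = None
    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(lines, start=1):
        if ln.startswith("##sequence-region"):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: malformed sequence-region pragma")
            chrom = Chromosome(name=parts[1], length_bp=int(parts[3]), circular=True)
            continue
        if not ln or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
        if f[2] != "CDS":
            continue
        attrs = _parse_gff_attributes(f[8])
        if "ID" not in attrs:
            raise ParseError(f"{path}:{lineno}: CDS feature without ID attribute")
        gid = attrs["ID"]
        if gid in seen:
            raise LoadError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        start, end = int(f[3]), int(f[4])
        if "length_aa" in attrs:
            length_aa = int(attrs["length_aa"])
        else:
            # derive protein length from the nucleotide span minus the stop codon
            span = end - start + 1 if end >= start else None
            if span is None or span % 3 != 0:
                raise LoadError(
                    f"{path}:{lineno}: cannot derive length_aa for {gid!r}; "
                    "add a length_aa attribute"
                )
            length_aa = span // 3 - 1
        genes.append(
            Gene(
                gene_id=gid,
                start=start,
                end=end,
                strand=f[6],
                length_aa=length_aa,
                product=attrs.get("product", ""),
                cog=attrs.get("cog"),
            )
        )
    if chrom is None:
        raise LoadError(f"{path}: missing ##sequence-region pragma")
    for g in genes:
        _check_gene_coords(g, chrom)
    return _sort_genes(genes), chrom


def write_gene_table(genes: Sequence[Gene], chrom: Chromosome, path: str) -> None:
    lines = [
        f"# chromosome={chrom.name}",
        f"# length_bp={chrom.length_bp}",
        f"# circular={'true' if chrom.circular else 'false'}",
        "\t".join(GENE_TSV_COLUMNS),
    ]
    for g in genes:
        lines.append(
            "\t".join(
                [
                    g.gene_id,
                    str(g.start),
                    str(g.end),
                    g.strand,
                    str(g.length_aa),
                    g.product,
                    g.cog or "",
                ]
            )
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_hit_table(path: str, genes: Sequence[Gene]) -> list[Hit]:
    """Parse an extended BLAST-tabular hit table.

    Rows referencing a query_id absent from ``genes`` are rejected; coverage
    is computed from the query protein length.
    """
    length_by_id = {g.gene_id: g.length_aa for g in genes}
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            f = ln.split("\t")
            if f[0] == "query_id":  # optional header row
                continue
            if len(f) < len(HIT_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected >= 7 columns")
            qid = f[0]
            if qid not in length_by_id:
                raise LoadError(f"{path}:{lineno}: unknown query_id {qid!r}")
            try:
                sim = float(f[3])
                qs, qe = int(f[4]), int(f[5])
                score = float(f[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            hits.append(
                make_hit(qid, f[1], f[2], sim, qs, qe, score, length_by_id[qid])
            )
    return hits


def write_hit_table(hits: Iterable[Hit], path: str) -> None:
    lines = ["\t".join(HIT_COLUMNS)]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    h.subject_taxon,
                    f"{h.percent_similarity:.2f}",
                    str(h.align_q_start),
                    str(h.align_q_end),
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_taxonomy(path: str) -> TaxonomyMap:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = _read_sidecar(lines)
    if "focal_clade" not in meta or "focal_taxon" not in meta:
        raise LoadError(
            f"{path}: taxonomy file needs '# focal_clade=' and '# focal_taxon=' headers"
        )
    entries: dict[str, str] = {}
    for lineno, ln in enumerate(lines, start=1):
        if not ln or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if f[0] == "taxon":
            continue
        if len(f) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'taxon<TAB>clade'")
        entries[f[0]] = f[1]
    return TaxonomyMap(
        entries=entries, focal_clade=meta["focal_clade"], focal_taxon=meta["focal_taxon"]
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str) -> None:
    lines = [
        f"# focal_clade={taxonomy.focal_clade}",
        f"# focal_taxon={taxonomy.focal_taxon}",
        "taxon\tclade",
    ]
    for taxon, clade in taxonomy.entries.items():
        lines.append(f"{taxon}\t{clade}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_fasta(path: str, circular: bool = True) -> Chromosome:
    """Read a single-record FASTA; only A/C/G/T/N are accepted."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise LoadError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise LoadError(
            f"{path}: ambiguity codes other than N are not supported: {sorted(bad)}"
        )
    return Chromosome(name=rec.id, length_bp=len(seq), sequence=seq, circular=circular)


def write_fasta(chrom: Chromosome, path: str, width: int = 70) -> None:
    if chrom.sequence is None:
        raise ValueError("chromosome has no sequence to write")
    lines = [f">{chrom.name}"]
    for i in range(0, len(chrom.sequence), width):
        lines.append(chrom.sequence[i : i + width])
    _atomic_write(path, "\n".join(lines) + "\n")


def write_calls_table(calls: Sequence[OriginCall], path: str) -> None:
    lines = ["\t".join(CALL_COLUMNS)]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.gene_id,
                    c.origin_class,
                    c.donor_clade or "",
                    "1" if c.donor_tentative else "0",
                    str(c.n_focal_hits),
                    str(c.n_nonfocal_hits),
                    ",".join(c.top_subjects),
                ]
            )
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_calls_table(path: str) -> list[OriginCall]:
    """Reload a per-gene calls TSV (evidence hits are not round-tripped)."""
    calls: list[OriginCall] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#") or ln.startswith("gene_id\t"):
                continue
            f = ln.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
            subjects = tuple(s for s in (f[6].split(",") if len(f) > 6 and f[6] else []))
            calls.append(
                OriginCall(
                    gene_id=f[0],
                    origin_class=f[1],
                    donor_clade=f[2] or None,
                    donor_tentative=f[3] == "1",
                    n_focal_hits=int(f[4]),
                    n_nonfocal_hits=int(f[5]),
                    top_subjects=subjects,
                )
            )
    return calls


def islands_to_bed_lines(islands: Sequence[Island], chrom: Chromosome) -> list[str]:
    """Render islands as BED intervals (0-based half-open).

    An origin-wrapping island becomes two lines sharing the island name.
    """
    lines = ["# islands of same-donor acquired genes; BED 0-based half-open"]
    for isl in islands:
        if not isl.wraps_origin:
            lines.append(
                f"{chrom.name}\t{isl.span_start - 1}\t{isl.span_end}\t{isl.island_id}"
            )
        else:
            lines.append(
                f"{chrom.name}\t{isl.span_start - 1}\t{chrom.length_bp}\t{isl.island_id}"
            )
            lines.append(f"{chrom.name}\t0\t{isl.span_end}\t{isl.island_id}")
    return lines


def write_reports(
    calls: Sequence[OriginCall],
    islands: Sequence[Island],
    summary: dict,
    out_dir: str,
    chrom: Chromosome,
) -> dict[str, str]:
    """Write the per-gene calls TSV, islands BED, and summary JSON atomically.

    Fails before any partial file persists if the directory is unwritable.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")
    paths = {
        "calls": os.path.join(out_dir, "calls.tsv"),
        "islands": os.path.join(out_dir, "islands.bed"),
        "summary": os.path.join(out_dir, "summary.json"),
    }
    write_calls_table(calls, paths["calls"])
    _atomic_write(paths["islands"], "\n".join(islands_to_bed_lines(islands, chrom)) + "\n")
    _atomic_write(paths["summary"], json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
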