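"""Synthetic genomes with planted gene-origin truth.

The generator emits everything the pipeline consumes — gene table,
chromosome FASTA, taxonomy map, raw hit table — from a planted truth
labelling, so every stage can be tested against known answers without any
database download.  What it emulates is the *statistical structure* the
classifier relies on (taxonomic composition of ranked, filtered hit lists),
not BLAST realism: bit scores decrease with intended rank, and similarity
and coverage are drawn on the intended side of the filter thresholds.

Defaults mirror the flagship study conditions: 1,346 protein-coding genes
on a 1.56 Mb circular chromosome, class counts 641/472/142/91, seven
planted acquired islands totalling 45 genes, nine gene-tree candidates, and
donor-clade weights 0.38/0.13/0.17/0.32.  Donor clades and COG letters of
acquired genes are assigned by largest-remainder quota over the configured
weights so fixture composition matches the configuration exactly.

A configurable fraction of hits is placed *borderline* — within a small
band around the strict similarity threshold — and recorded in the truth
table.  With similarity noise switched on, only such borderline hits can
flip across the threshold, so every misclassified gene is guaranteed to
carry at least one recorded borderline hit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .model import Chromosome, ConfigError, Gene, Hit, OriginCall, TaxonomyMap, make_hit

CLASSES = ("native", "species_specific", "hgt_low", "hgt_high")

_DEFAULT_DONORS = {
    "Mycoides-Entomoplasmataceae": 0.38,
    "Citri-Chrysopicola-Mirum": 0.13,
    "other-Mollicutes": 0.17,
    "non-Mollicutes": 0.32,
}

# mean protein lengths per class (aa); orphan genes run shorter, matching
# the tendency of species-specific ORFs to be short hypothetical proteins
_DEFAULT_MEAN_AA = {
    "native": 365,
    "species_specific": 318,
    "hgt_low": 328,
    "hgt_high": 342,
}

_DEFAULT_COG = {
    "G": 0.51,
    "E": 0.09,
    "P": 0.08,
    "C": 0.06,
    "M": 0.05,
    "R": 0.08,
    "unassigned": 0.13,
}

_BACKGROUND_COG = "JKLMNOPQRSTUVCEFGHID"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome."""

    seed: int
    n_genes: int = 1346
    chrom_len_bp: int = 1_560_000
    class_fractions: tuple = (641 / 1346, 472 / 1346, 142 / 1346, 91 / 1346)
    donor_clades: dict = field(default_factory=lambda: dict(_DEFAULT_DONORS))
    n_islands: int = 7
    island_sizes: Optional[tuple] = (7, 7, 7, 6, 6, 6, 6)
    island_size_range: tuple = (5, 8)
    hits_per_gene_range: tuple = (6, 12)
    similarity_noise_sd: float = 0.0
    borderline_fraction: float = 0.0
    n_tree_candidates: int = 9
    tree_candidate_homolog_range: tuple = (5, 7)
    mean_length_aa: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_AA))
    cog_probs_acquired: dict = field(default_factory=lambda: dict(_DEFAULT_COG))
    base_gc: float = 0.26
    island_gc_delta: float = 0.0
    focal_clade: str = "Apis"
    focal_taxon: str = "Spiroplasma clarkii"
    n_focal_taxa: int = 10
    taxa_per_donor_clade: int = 12
    min_member_spacing: int = 4  # genes between planted acquired features

    def class_counts(self) -> dict[str, int]:
        return dict(zip(CLASSES, _largest_remainder(self.n_genes, self.class_fractions)))

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory (no implicit entropy)")
        if len(self.class_fractions) != 4 or any(f < 0 for f in self.class_fractions):
            raise ConfigError("class_fractions must be four nonnegative numbers")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ConfigError("class_fractions must sum to 1")
        if not self.donor_clades or any(w < 0 for w in self.donor_clades.values()):
            raise ConfigError("donor_clades needs nonnegative weights")
        counts = self.class_counts()
        sizes = self.island_sizes
        if sizes is not None and len(sizes) != self.n_islands:
            raise ConfigError("island_sizes length must equal n_islands")
        min_island_total = (
            sum(sizes) if sizes is not None else self.n_islands * self.island_size_range[0]
        )
        if min_island_total > counts["hgt_high"]:
            raise ConfigError(
                f"islands demand {min_island_total} acquired genes but the class "
                f"fraction allows only {counts['hgt_high']}"
            )
        if self.n_tree_candidates > counts["hgt_high"]:
            raise ConfigError("more tree candidates requested than acquired genes")
        # rough placement feasibility: every planted acquired feature needs
        # spacing so scattered genes cannot chain into spurious islands
        scattered = counts["hgt_high"] - min_island_total
        need = min_island_total + (self.n_islands + scattered) * self.min_member_spacing
        if need > self.n_genes:
            raise ConfigError("too few genes to place islands with the required spacing")
        if not (0 <= self.borderline_fraction <= 1):
            raise ConfigError("borderline_fraction must be in [0,1]")
        if self.similarity_noise_sd < 0:
            raise ConfigError("similarity_noise_sd must be >= 0")


@dataclass
class TruthRecord:
    gene_id: str
    true_class: str
    true_donor: str = ""
    island_id: str = ""
    is_tree_candidate: bool = False
    borderline_hit_ids: tuple = ()

    @property
    def is_island_member(self) -> bool:
        return bool(self.island_id)


@dataclass
class FixtureBundle:
    config: SimulationConfig
    genes: list
    chromosome: Chromosome
    taxonomy: TaxonomyMap
    hits: list
    truth: list

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.gene_id: t for t in self.truth}

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "genes": os.path.join(out_dir, "genes.tsv"),
            "fasta": os.path.join(out_dir, "chromosome.fasta"),
            "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
            "hits": os.path.join(out_dir, "hits.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        gio.write_gene_table(self.genes, self.chromosome, paths["genes"])
        gio.write_fasta(self.chromosome, paths["fasta"])
        gio.write_taxonomy(self.taxonomy, paths["taxonomy"])
        gio.write_hit_table(self.hits, paths["hits"])
        write_truth_table(self.truth, paths["truth"])
        return paths


def write_truth_table(truth: Sequence[TruthRecord], path: str) -> None:
    lines = ["gene_id\ttrue_class\ttrue_donor\tisland_id\tis_tree_candidate\tborderline_hit_ids"]
    for t in truth:
        lines.append(
            "\t".join(
                [
                    t.gene_id,
                    t.true_class,
                    t.true_donor,
                    t.island_id,
                    "1" if t.is_tree_candidate else "0",
                    ";".join(t.borderline_hit_ids),
                ]
            )
        )
    gio._atomic_write(path, "\n".join(lines) + "\n")


def read_truth_table(path: str) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        for ln in fh.read().splitlines():
            if not ln or ln.startswith("gene_id\t") or ln.startswith("#"):
                continue
            f = ln.split("\t")
            out.append(
                TruthRecord(
                    gene_id=f[0],
                    true_class=f[1],
                    true_donor=f[2],
                    island_id=f[3],
                    is_tree_candidate=f[4] == "1",
                    borderline_hit_ids=tuple(x for x in f[5].split(";") if x)
                    if len(f) > 5
                    else (),
                )
            )
    return out


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Integer apportionment of ``total`` by ``weights`` (largest remainder)."""
    s = float(sum(weights))
    quotas = [total * w / s for w in weights]
    floors = [int(np.floor(q)) for q in quotas]
    short = total - sum(floors)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def _build_taxonomy(cfg: SimulationConfig) -> tuple[TaxonomyMap, dict[str, list[str]]]:
    entries = {cfg.focal_taxon: cfg.focal_clade}
    focal = [f"{cfg.focal_clade} clade sp. {i:02d}" for i in range(1, cfg.n_focal_taxa + 1)]
    for t in focal:
        entries[t] = cfg.focal_clade
    per_clade: dict[str, list[str]] = {cfg.focal_clade: focal}
    for clade in cfg.donor_clades:
        taxa = [f"{clade} sp. {i:02d}" for i in range(1, cfg.taxa_per_donor_clade + 1)]
        for t in taxa:
            entries[t] = clade
        per_clade[clade] = taxa
    return (
        TaxonomyMap(entries=entries, focal_clade=cfg.focal_clade, focal_taxon=cfg.focal_taxon),
        per_clade,
    )


def _place_features(cfg: SimulationConfig, rng: np.random.Generator):
    """Choose island blocks and scattered acquired positions with spacing.

    Spacing (``min_member_spacing`` interleaving genes) guarantees that the
    default gap rule cannot chain two distinct planted features together, so
    detection ground truth is exact.
    """
    counts = cfg.class_counts()
    if cfg.island_sizes is not None:
        sizes = list(cfg.island_sizes)
    else:
        lo, hi = cfg.island_size_range
        sizes = list(rng.integers(lo, hi + 1, size=cfg.n_islands))
    spacing = cfg.min_member_spacing
    n = cfg.n_genes

    # lay island blocks around the circle separated by random slack
    total_blocks = sum(sizes) + spacing * len(sizes)
    free = n - total_blocks
    if free < 0:
        raise ConfigError("islands do not fit on the gene circle")
    slack = rng.multinomial(free, [1.0 / len(sizes)] * len(sizes)) if sizes else []
    island_positions: list[list[int]] = []
    cursor = int(rng.integers(0, n))
    for k, size in enumerate(sizes):
        cursor = (cursor + spacing + int(slack[k])) % n
        island_positions.append([(cursor + j) % n for j in range(size)])
        cursor = (cursor + size) % n

    taken = {i for blk in island_positions for i in blk}
    blocked = set(taken)
    for blk in island_positions:
        for j in range(1, spacing + 1):
            blocked.add((blk[0] - j) % n)
            blocked.add((blk[-1] + j) % n)

    n_scatter = counts["hgt_high"] - sum(sizes)
    scattered = _spaced_positions(n, blocked, spacing, n_scatter, rng)
    return counts, sizes, island_positions, sorted(scattered)


def _spaced_positions(n, blocked, spacing, n_pick, rng) -> list[int]:
    """Pick ``n_pick`` unblocked positions pairwise > ``spacing`` apart.

    Free stretches between blocked zones are carved into slots every
    ``spacing + 1`` genes (random per-segment offset); picking any subset of
    slots preserves the separation guarantee.
    """
    free = [i for i in range(n) if i not in blocked]
    if not free and n_pick:
        raise ConfigError("could not place scattered acquired genes with spacing")
    segments: list[list[int]] = []
    for i in free:
        if segments and i == segments[-1][-1] + 1:
            segments[-1].append(i)
        else:
            segments.append([i])
    # merge a wrap-around pair of segments on the circle
    if len(segments) > 1 and segments[0][0] == 0 and segments[-1][-1] == n - 1:
        segments[0] = segments.pop() + segments[0]
    slots: list[int] = []
    for seg in segments:
        offset = int(rng.integers(0, min(spacing + 1, len(seg))))
        seg_slots = seg[offset :: spacing + 1]
        if len(seg) == n:  # full circle: respect spacing across the wrap too
            seg_slots = seg_slots[: max(1, n // (spacing + 1))]
        slots.extend(seg_slots)
    if len(slots) < n_pick:
        raise ConfigError("could not place scattered acquired genes with spacing")
    rng.shuffle(slots)
    return slots[:n_pick]


def _assign_donors(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sizes: list[int],
    n_scatter: int,
) -> tuple[list[str], list[str]]:
    """Quota-assign donor clades to islands and scattered acquired genes."""
    clades = sorted(cfg.donor_clades)
    weights = [cfg.donor_clades[c] for c in clades]
    total = sum(sizes) + n_scatter
    quota = dict(zip(clades, _largest_remainder(total, weights)))
    island_donors: list[str] = []
    for size in sizes:
        eligible = [c for c in clades if quota[c] >= size] or clades
        pick = max(eligible, key=lambda c: (quota[c], c))
        island_donors.append(pick)
        quota[pick] -= size
    pool: list[str] = []
    for c in clades:
        pool.extend([c] * max(quota[c], 0))
    while len(pool) < n_scatter:  # quota went negative on an island pick
        pool.append(clades[int(rng.integers(len(clades)))])
    rng.shuffle(pool)
    return island_donors, pool[:n_scatter]


def _assign_cogs(cfg: SimulationConfig, rng, class_of: list[str]) -> list[Optional[str]]:
    n = len(class_of)
    cogs: list[Optional[str]] = [None] * n
    acquired_idx = [i for i in range(n) if class_of[i] == "hgt_high"]
    letters = sorted(cfg.cog_probs_acquired)
    alloc = _largest_remainder(
        len(acquired_idx), [cfg.cog_probs_acquired[k] for k in letters]
    )
    pool: list[Optional[str]] = []
    for letter, k in zip(letters, alloc):
        pool.extend([None if letter == "unassigned" else letter] * k)
    rng.shuffle(pool)
    for i, letter in zip(acquired_idx, pool):
        cogs[i] = letter
    for i in range(n):
        if class_of[i] != "hgt_high":
            if rng.random() < 0.75:
                cogs[i] = _BACKGROUND_COG[int(rng.integers(len(_BACKGROUND_COG)))]
    return cogs


def _gene_layout(cfg: SimulationConfig, rng, class_of: list[str], cogs) -> list[Gene]:
    n = cfg.n_genes
    lengths = []
    for cls in class_of:
        mean = cfg.mean_length_aa[cls]
        lengths.append(int(np.clip(rng.normal(mean, 0.3 * mean), 80, 1200)))
    spans = [3 * L + 3 for L in lengths]
    total_span = sum(spans)
    if total_span >= cfg.chrom_len_bp:
        raise ConfigError(
            f"gene spans ({total_span} bp) exceed chromosome length ({cfg.chrom_len_bp} bp)"
        )
    gaps = rng.multinomial(cfg.chrom_len_bp - total_span, [1.0 / n] * n)
    genes = []
    cur = 1
    for i in range(n):
        start = cur
        end = start + spans[i] - 1
        genes.append(
            Gene(
                gene_id=f"g{i + 1:04d}",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                length_aa=lengths[i],
                product="hypothetical protein",
                cog=cogs[i],
            )
        )
        cur = end + 1 + int(gaps[i])
    return genes


class _HitFactory:
    """Builds hit rows with controlled filter behaviour and rank order."""

    def __init__(self, cfg: SimulationConfig, rng, per_clade: dict[str, list[str]]):
        self.cfg = cfg
        self.rng = rng
        self.per_clade = per_clade
        self.counter = 0
        self.eps = max(1.0, 2.0 * cfg.similarity_noise_sd)

    def subject(self, taxon: str) -> str:
        self.counter += 1
        return f"{taxon.replace(' ', '_')}|p{self.counter:06d}"

    def taxon(self, clade: str, exclude_focal_self: bool = True) -> str:
        taxa = self.per_clade[clade]
        return taxa[int(self.rng.integers(len(taxa)))]

    def _coverage_span(self, L: int, lo: float, hi: float, mode: str) -> tuple[int, int]:
        c = self.rng.uniform(lo, hi)
        span = int(np.ceil(c * L)) if mode == "ceil" else int(np.floor(c * L))
        span = min(max(span, 1), L)
        qs = 1 + int(self.rng.integers(0, L - span + 1))
        return qs, qs + span - 1

    def make(self, gene: Gene, taxon: str, score: float, role: str, borderline: bool):
        """One hit row; role governs which filters it is meant to pass.

        Roles: ``pass_strict`` (passes both filters), ``relaxed_only``
        (fails strict, passes relaxed), ``fail`` (fails both).  Returns
        (Hit, borderline_flag).
        """
        rng, L = self.rng, gene.length_aa
        if role == "pass_strict":
            if borderline and rng.random() < 0.3:
                # boundary-exact coverage; similarity comfortably passing
                span = int(np.ceil(0.90 * L))
                qs = 1 + int(rng.integers(0, L - span + 1))
                qe = qs + span - 1
                sim = rng.uniform(55.0, 95.0)
            else:
                qs, qe = self._coverage_span(L, 0.92, 1.0, "ceil")
                sim = (
                    40.0 + rng.uniform(0.0, self.eps)
                    if borderline
                    else rng.uniform(55.0, 95.0)
                )
        elif role == "relaxed_only":
            qs, qe = self._coverage_span(L, 0.82, 0.88, "ceil")
            sim = rng.uniform(32.0, 38.0)
            borderline = False
        elif role == "fail":
            if borderline:
                # just under the strict similarity threshold, coverage passing,
                # so similarity noise can flip it into the strict set
                qs, qe = self._coverage_span(L, 0.92, 1.0, "ceil")
                sim = 40.0 - rng.uniform(0.05, self.eps)
            else:
                qs, qe = self._coverage_span(L, 0.45, 0.75, "floor")
                sim = rng.uniform(15.0, 28.0)
        else:
            raise ValueError(role)

        if self.cfg.similarity_noise_sd > 0:
            sim += rng.normal(0.0, self.cfg.similarity_noise_sd)
            if not borderline:
                # noise never flips a comfortably-placed hit across a threshold
                if role == "pass_strict":
                    sim = max(sim, 42.0)
                elif role == "relaxed_only":
                    sim = float(np.clip(sim, 32.0, 38.0))
                else:
                    sim = min(sim, 28.0)
        sim = float(np.clip(sim, 0.0, 100.0))
        hit = make_hit(
            gene.gene_id, self.subject(taxon), taxon, sim, qs, qe, score, L
        )
        return hit, borderline


def generate(cfg: SimulationConfig) -> FixtureBundle:
    """Generate a complete fixture bundle from planted truth labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts, sizes, island_positions, scattered = _place_features(cfg, rng)
    n = cfg.n_genes

    class_of = [""] * n
    island_of = [""] * n
    donor_of = [""] * n
    island_donors, scatter_donors = _assign_donors(cfg, rng, sizes, len(scattered))
    for k, blk in enumerate(island_positions):
        for i in blk:
            class_of[i] = "hgt_high"
            island_of[i] = f"planted_island_{k + 1}"
            donor_of[i] = island_donors[k]
    for i, d in zip(scattered, scatter_donors):
        class_of[i] = "hgt_high"
        donor_of[i] = d

    rest = [i for i in range(n) if not class_of[i]]
    rng.shuffle(rest)
    pos = 0
    for cls in ("native", "species_specific", "hgt_low"):
        for i in rest[pos : pos + counts[cls]]:
            class_of[i] = cls
        pos += counts[cls]
    donor_names = sorted(cfg.donor_clades)
    donor_w = np.array([cfg.donor_clades[c] for c in donor_names], dtype=float)
    donor_w /= donor_w.sum()
    for i in range(n):
        if class_of[i] == "hgt_low":
            donor_of[i] = donor_names[int(rng.choice(len(donor_names), p=donor_w))]

    hgt_high_idx = [i for i in range(n) if class_of[i] == "hgt_high"]
    cand_pick = rng.choice(len(hgt_high_idx), size=cfg.n_tree_candidates, replace=False)
    tree_candidates = {hgt_high_idx[int(j)] for j in cand_pick}

    cogs = _assign_cogs(cfg, rng, class_of)
    genes = _gene_layout(cfg, rng, class_of, cogs)
    taxonomy, per_clade = _build_taxonomy(cfg)
    factory = _HitFactory(cfg, rng, per_clade)
    focal_others = per_clade[cfg.focal_clade]

    hits: list[Hit] = []
    truth: list[TruthRecord] = []
    lo_hits, hi_hits = cfg.hits_per_gene_range
    for i, gene in enumerate(genes):
        cls = class_of[i]
        total_rows = int(rng.integers(lo_hits, hi_hits + 1))
        # roles in intended rank order (best first)
        roles: list[tuple[str, str]] = []  # (role, taxon)
        if cls == "native":
            n_pass = min(total_rows, int(rng.integers(3, 9)))
            n_pass = max(1, n_pass)
            for _ in range(n_pass):
                roles.append(("pass_strict", factory.taxon(cfg.focal_clade)))
            for _ in range(max(0, total_rows - n_pass)):
                clade = donor_names[int(rng.integers(len(donor_names)))]
                roles.append(("fail", factory.taxon(clade)))
        elif cls == "hgt_high":
            donor = donor_of[i]
            n_donor = int(rng.integers(5, 8))
            for _ in range(n_donor):
                roles.append(("pass_strict", factory.taxon(donor)))
            n_below_focal = int(rng.integers(0, 4))  # strict-passing but outranked
            for _ in range(n_below_focal):
                roles.append(("pass_strict", factory.taxon(cfg.focal_clade)))
            if i in tree_candidates:
                lo_c, hi_c = cfg.tree_candidate_homolog_range
                k = int(rng.integers(max(lo_c, 5), hi_c + 1))
                for _ in range(k):
                    roles.append(("relaxed_only", factory.taxon(cfg.focal_clade)))
            for _ in range(max(0, total_rows - len(roles))):
                clade = donor_names[int(rng.integers(len(donor_names)))]
                roles.append(("fail", factory.taxon(clade)))
        elif cls == "hgt_low":
            donor = donor_of[i]
            n_focal = int(rng.integers(1, 5))
            top5 = ["focal"] * n_focal + ["donor"] * (5 - n_focal)
            rng.shuffle(top5)
            for kind in top5:
                taxon = (
                    factory.taxon(cfg.focal_clade) if kind == "focal" else factory.taxon(donor)
                )
                roles.append(("pass_strict", taxon))
            for _ in range(max(0, total_rows - 5)):
                clade = donor_names[int(rng.integers(len(donor_names)))]
                roles.append(("fail", factory.taxon(clade)))
        else:  # species_specific
            if rng.random() < 0.5:
                roles = []
            else:
                for _ in range(int(rng.integers(1, 5))):
                    clade = donor_names[int(rng.integers(len(donor_names)))]
                    roles.append(("fail", factory.taxon(clade)))

        borderline_ids: list[str] = []
        base = rng.uniform(400.0, 900.0)
        for rank, (role, taxon) in enumerate(roles):
            score = base - 8.0 * rank - rng.uniform(0.0, 4.0)
            borderline = (
                role in ("pass_strict", "fail")
                and rng.random() < cfg.borderline_fraction
            )
            hit, borderline = factory.make(gene, taxon, max(score, 10.0), role, borderline)
            hits.append(hit)
            if borderline:
                borderline_ids.append(hit.hit_id)
        # occasionally include the self-hit the real search would return
        if cls != "species_specific" and rng.random() < 0.7:
            hits.append(
                make_hit(
                    gene.gene_id,
                    gene.gene_id,
                    cfg.focal_taxon,
                    100.0,
                    1,
                    gene.length_aa,
                    base + 100.0,
                    gene.length_aa,
                )
            )
        truth.append(
            TruthRecord(
                gene_id=gene.gene_id,
                true_class=cls,
                true_donor=donor_of[i],
                island_id=island_of[i],
                is_tree_candidate=i in tree_candidates,
                borderline_hit_ids=tuple(borderline_ids),
            )
        )

    sequence = _chromosome_sequence(cfg, rng, genes, island_of)
    chrom = Chromosome(
        name="chr", length_bp=cfg.chrom_len_bp, sequence=sequence, circular=True
    )
    return FixtureBundle(
        config=cfg, genes=genes, chromosome=chrom, taxonomy=taxonomy, hits=hits, truth=truth
    )


def _chromosome_sequence(cfg, rng, genes, island_of) -> str:
    gc = cfg.base_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=cfg.chrom_len_bp, p=p)
    if cfg.island_gc_delta != 0.0:
        gc2 = float(np.clip(gc + cfg.island_gc_delta, 0.05, 0.95))
        p2 = np.array([(1 - gc2) / 2, gc2 / 2, gc2 / 2, (1 - gc2) / 2])
        for g, isl in zip(genes, island_of):
            if isl:
                seg = rng.choice(bases, size=g.end - g.start + 1, p=p2)
                seq[g.start - 1 : g.end] = seg
    return seq.tobytes().decode("ascii")


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame
    per_class_accuracy: dict
    overall_accuracy: float
    island_precision: Optional[float] = None
    island_recall: Optional[float] = None
    n_misclassified: int = 0
    misclassified_gene_ids: tuple = ()


def evaluate_recovery(
    calls: Sequence[OriginCall],
    truth: Sequence[TruthRecord],
    detected_islands: Optional[Sequence] = None,
) -> RecoveryReport:
    """Score classification (4x4 confusion) and optionally island recovery.

    A detected island matches a planted one when the Jaccard index of their
    member gene sets is >= 0.5; matching is greedy one-to-one in decreasing
    Jaccard order.
    """
    truth_by_id = {t.gene_id: t for t in truth}
    if {c.gene_id for c in calls} != set(truth_by_id):
        raise ValueError("calls and truth do not cover the same gene set")
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    mis: list[str] = []
    for c in calls:
        t = truth_by_id[c.gene_id].true_class
        mat.loc[t, c.origin_class] += 1
        if t != c.origin_class:
            mis.append(c.gene_id)
    per_class = {}
    for cls in CLASSES:
        row_total = int(mat.loc[cls].sum())
        per_class[cls] = float(mat.loc[cls, cls]) / row_total if row_total else float("nan")
    overall = float(np.trace(mat.values)) / len(calls)

    precision = recall = None
    if detected_islands is not None:
        planted: dict[str, set] = {}
        for t in truth:
            if t.island_id:
                planted.setdefault(t.island_id, set()).add(t.gene_id)
        pairs = []
        for d_i, isl in enumerate(detected_islands):
            d_set = set(isl.gene_ids)
            for p_id, p_set in planted.items():
                inter = len(d_set & p_set)
                if inter:
                    j = inter / len(d_set | p_set)
                    pairs.append((j, d_i, p_id))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_d: set[int] = set()
        used_p: set[str] = set()
        matches = 0
        for j, d_i, p_id in pairs:
            if j < 0.5 or d_i in used_d or p_id in used_p:
                continue
            used_d.add(d_i)
            used_p.add(p_id)
            matches += 1
        precision = matches / len(detected_islands) if detected_islands else float("nan")
        recall = matches / len(planted) if planted else float("nan")

    return RecoveryReport(
        confusion=mat,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        island_precision=precision,
        island_recall=recall,
        n_misclassified=len(mis),
        misclassified_gene_ids=tuple(mis),
    )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain (e.g. YAML-loaded) mapping."""
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("class_fractions", "island_sizes", "island_size_range",
                "hits_per_gene_range", "tree_candidate_homolog_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
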