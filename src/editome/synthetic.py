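"""Synthetic study generator: a fully specified toy editome experiment.

Generates a small annotated genome, planted A-to-I editing truth, matched
WGS genotypes, a known-SNP catalogue, mature miRNAs and per-sample
strand-specific RNA-seq site evidence, so that every downstream stage of
the pipeline is testable without external data.

What the generator emulates
---------------------------
* a multi-stage design (default 3 stages x 3 replicates) with stage mean
  editing levels matching the overall editing rates of a developing
  neuroendocrine tissue (puberty higher than infancy and adulthood);
* a porcine-like SINE repeat family ("SINE/tRNA:Pre0_SS-like") hosting the
  bulk of the editing sites, with realistically diverged copies;
* heterozygous genomic SNPs that surface in RNA at ~50% alternative allele;
* three planted artifact classes, each violating exactly one detection
  filter: read-end mismatches, homopolymer-run mismatches, and mismatches
  inside a duplicated (multi-mapping) segment.

Coordinates are 0-based half-open internally; writers emit the standard
1-based dialects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .io_formats import (
    GeneModel,
    ReferenceBundle,
    RepeatInterval,
    VcfRecord,
    revcomp,
)

__all__ = [
    "SizingError",
    "PlacementError",
    "TrueSite",
    "HetSnp",
    "ArtifactSite",
    "SyntheticTruth",
    "generate_reference",
    "plant_truth",
    "simulate_wgs_genotypes",
    "known_snp_records",
    "simulate_rna_evidence",
    "simulate_mirnas",
    "site_key",
    "maximal_run_lengths",
    "reverse_complement_bundle",
    "reverse_complement_evidence",
]


class SizingError(ValueError):
    """The requested genome cannot host the requested features."""


class PlacementError(ValueError):
    """Not enough eligible positions to place the requested truth."""


_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Divergence of planted repeat copies from the family consensus.  Old SINE
# copies in mammalian genomes have typically accumulated 10-20% substitutions;
# 15% keeps 51 bp windows of distinct copies well below the multi-mapping
# identity threshold while preserving family identity.
REPEAT_COPY_DIVERGENCE = 0.15
ARTIFACT_LEVEL = 0.3
HOMOPOLYMER_RUN = 7
DUP_MUTATION_SPACING = 60
_EDGE_MARGIN = 30
_JUNCTION_MARGIN = 6

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _rand_seq(rng: np.random.Generator, n: int, p: Optional[Sequence[float]] = None) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _make_repeat_consensus() -> str:
    """A fixed 180 nt A-rich SINE-like consensus (deterministic)."""
    rng = np.random.default_rng(977)
    return _rand_seq(rng, 180, p=[0.34, 0.16, 0.28, 0.22])


REPEAT_CONSENSUS = _make_repeat_consensus()


def site_key(chrom: str, pos: int, strand: str) -> str:
    """Stable 1-based site identifier ``chrom:pos:strand``."""
    return f"{chrom}:{pos + 1}:{strand}"


def parse_site_key(key: str) -> Tuple[str, int, str]:
    chrom, pos1, strand = key.rsplit(":", 2)
    return chrom, int(pos1) - 1, strand


def maximal_run_lengths(seq: str) -> np.ndarray:
    """Length of the maximal run of identical bases covering each position."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.nonzero(arr[1:] != arr[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    out = np.empty(n, dtype=np.int64)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueSite:
    chrom: str
    pos: int
    strand: str
    levels: Tuple[Tuple[str, float], ...]  # ((stage, true level), ...)

    def level(self, stage: str) -> float:
        return dict(self.levels)[stage]

    @property
    def key(self) -> str:
        return site_key(self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class HetSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str  # strand of the host gene (library strand in RNA)


@dataclass(frozen=True)
class ArtifactSite:
    chrom: str
    pos: int
    strand: str
    kind: str  # read_end | homopolymer | mismap


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    true_sites: List[TrueSite]
    het_snps: List[HetSnp]
    artifact_sites: List[ArtifactSite]
    background_positions: List[Tuple[str, int, str]]
    repeat_intervals: List[RepeatInterval]
    duplicated_segment: Tuple[Tuple[str, int, int], Tuple[str, int, int]]
    stages: List[str]

    def __post_init__(self) -> None:
        positions = (
            [(s.chrom, s.pos) for s in self.true_sites]
            + [(s.chrom, s.pos) for s in self.het_snps]
            + [(s.chrom, s.pos) for s in self.artifact_sites]
            + [(c, p) for c, p, _ in self.background_positions]
        )
        if len(positions) != len(set(positions)):
            raise PlacementError("planted positions collide")

    def sites_with_level_at_least(self, level: float) -> List[TrueSite]:
        return [
            s for s in self.true_sites if max(v for _, v in s.levels) >= level
        ]


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

@dataclass
class _Draft:
    """A gene drafted in local plus-sense coordinates."""

    seq: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]
    repeats: List[Tuple[int, int]]
    homopolymers: List[Tuple[int, int]]
    dup_src: Optional[Tuple[int, int]] = None
    biotype: str = "coding"


class _Builder:
    def __init__(self) -> None:
        self.chunks: List[str] = []
        self.cur = 0

    def add(self, seq: str) -> Tuple[int, int]:
        start = self.cur
        self.chunks.append(seq)
        self.cur += len(seq)
        return (start, self.cur)

    @property
    def seq(self) -> str:
        return "".join(self.chunks)


def _coding_gene_draft(
    rng: np.random.Generator, hp_runs: int, dup_seq: Optional[str]
) -> _Draft:
    b = _Builder()
    exons: List[Tuple[int, int]] = []
    cds: List[Tuple[int, int]] = []
    repeats: List[Tuple[int, int]] = []
    hps: List[Tuple[int, int]] = []
    k1, k2 = hp_runs - hp_runs // 2, hp_runs // 2

    exons.append(b.add(_rand_seq(rng, 120)))  # 5'-UTR exon
    b.add(_rand_seq(rng, 60))
    dup_src = b.add(dup_seq) if dup_seq is not None else None
    b.add(_rand_seq(rng, 40))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    for _ in range(k1):
        b.add(_rand_seq(rng, 12))
        hps.append(b.add("A" * HOMOPOLYMER_RUN))
    b.add(_rand_seq(rng, 40))

    cds1 = "ATG" + "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 79)
    )
    iv = b.add(cds1)  # 240 nt
    exons.append(iv)
    cds.append(iv)

    b.add(_rand_seq(rng, 60))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    for _ in range(k2):
        b.add(_rand_seq(rng, 12))
        hps.append(b.add("A" * HOMOPOLYMER_RUN))
    b.add(_rand_seq(rng, 40))

    ex3_start = b.cur
    cds2 = "".join(_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), 40))
    cds.append(b.add(cds2))  # 120 nt; total CDS 360 nt
    b.add(_rand_seq(rng, 80))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    b.add(_rand_seq(rng, 50))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    b.add(_rand_seq(rng, 80))
    exons.append((ex3_start, b.cur))

    return _Draft(b.seq, exons, cds, repeats, hps, dup_src, "coding")


def _lnc_gene_draft(rng: np.random.Generator, biotype: str) -> _Draft:
    b = _Builder()
    exons: List[Tuple[int, int]] = []
    repeats: List[Tuple[int, int]] = []
    exons.append(b.add(_rand_seq(rng, 150)))
    b.add(_rand_seq(rng, 80))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    b.add(_rand_seq(rng, 60))
    ex2_start = b.cur
    b.add(_rand_seq(rng, 60))
    repeats.append(b.add(_mutate(rng, REPEAT_CONSENSUS, REPEAT_COPY_DIVERGENCE)))
    b.add(_rand_seq(rng, 60))
    exons.append((ex2_start, b.cur))
    return _Draft(b.seq, exons, [], repeats, [], None, biotype)


def _flip_interval(iv: Tuple[int, int], length: int) -> Tuple[int, int]:
    return (length - iv[1], length - iv[0])


def _dup_source(rng: np.random.Generator, length: int) -> str:
    """Adenosine-anchored sequence: every third base is A (no long runs)."""
    others = np.array(list("CGT"))
    out = []
    for i in range(length):
        out.append("A" if i % 3 == 0 else others[rng.integers(0, 3)])
    return "".join(out)


def _dup_copy(rng: np.random.Generator, src: str) -> str:
    """Copy of the duplication source with substitutions every 60 bp.

    The fixed spacing guarantees that every 51 bp window of the source
    differs from the copy by at most one base, i.e. stays above any
    multi-mapping identity threshold up to 50/51.
    """
    arr = list(src)
    for i in range(DUP_MUTATION_SPACING // 2, len(arr), DUP_MUTATION_SPACING):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_reference(config: SimConfig, chrom: str = "chr1") -> ReferenceBundle:
    """Generate the synthetic reference bundle.

    The genome contains coding genes on both strands (5'-UTR / CDS / 3'-UTR
    / introns), long non-coding genes when ``n_genes`` allows, diverged
    copies of a SINE-like repeat family inside introns and 3'-UTRs,
    homopolymer tracts inside transcribed regions, and one near-identical
    duplicated segment.  Identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    if n_genes >= 4:
        biotypes = ["coding"] * (n_genes - 2) + ["lincRNA", "novel_lncRNA"]
    elif n_genes == 3:
        biotypes = ["coding", "coding", "lincRNA"]
    elif n_genes == 2:
        biotypes = ["coding", "coding"]
    else:
        raise SizingError(
            f"n_genes={n_genes} cannot satisfy 'at least one coding gene per "
            "strand' (need n_genes >= 2)"
        )
    n_coding = biotypes.count("coding")

    n_hp = max(1, config.n_homopolymer_artifacts)
    hp_per_gene = [
        n_hp // n_coding + (1 if i < n_hp % n_coding else 0) for i in range(n_coding)
    ]
    dup_len = max(240, 3 * config.n_mismap_artifacts + 180)
    dup_src_seq = _dup_source(rng, dup_len)

    genome = _Builder()
    gene_models: List[GeneModel] = []
    repeats: List[RepeatInterval] = []
    hp_runs: List[Tuple[int, int, str]] = []
    dup_a: Optional[Tuple[int, int]] = None

    coding_seen = 0
    for i, biotype in enumerate(biotypes):
        strand = "+" if i % 2 == 0 else "-"
        if biotype == "coding":
            draft = _coding_gene_draft(
                rng, hp_per_gene[coding_seen], dup_src_seq if coding_seen == 0 else None
            )
            coding_seen += 1
        else:
            draft = _lnc_gene_draft(rng, biotype)
        genome.add(_rand_seq(rng, 300))  # intergenic spacer
        L = len(draft.seq)
        if strand == "-":
            seq = revcomp(draft.seq)
            flip = lambda iv: _flip_interval(iv, L)  # noqa: E731
        else:
            seq = draft.seq
            flip = lambda iv: iv  # noqa: E731
        offset, _ = genome.add(seq)
        shift = lambda iv: (iv[0] + offset, iv[1] + offset)  # noqa: E731
        exons = sorted(shift(flip(iv)) for iv in draft.exons)
        cds = sorted(shift(flip(iv)) for iv in draft.cds)
        gene_models.append(
            GeneModel(
                gene_id=f"gene{i + 1}",
                transcript_id=f"gene{i + 1}.t1",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                biotype=biotype,
            )
        )
        for iv in draft.repeats:
            s, e = shift(flip(iv))
            repeats.append(
                RepeatInterval(chrom, s, e, "SINE/tRNA", "Pre0_SS-like", strand)
            )
        for iv in draft.homopolymers:
            s, e = shift(flip(iv))
            hp_runs.append((s, e, strand))
        if draft.dup_src is not None:
            s, e = shift(flip(draft.dup_src))
            dup_a = (s, e)

    genome.add(_rand_seq(rng, 300))
    dup_b = genome.add(_dup_copy(rng, dup_src_seq))
    genome.add(_rand_seq(rng, 100))

    needed = genome.cur
    if needed > config.genome_length:
        raise SizingError(
            f"genome_length={config.genome_length} is too short: the requested "
            f"features (n_genes={n_genes}, homopolymer/mismap artifact tracts) "
            f"need at least {needed} bp"
        )
    genome.add(_rand_seq(rng, config.genome_length - needed))

    assert dup_a is not None
    return ReferenceBundle(
        sequences={chrom: genome.seq},
        gene_models=gene_models,
        repeats=repeats,
        extras={
            "duplicated_segment": (
                (chrom, dup_a[0], dup_a[1]),
                (chrom, dup_b[0], dup_b[1]),
            ),
            "homopolymer_runs": [(chrom, s, e, st) for s, e, st in hp_runs],
        },
    )


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

def _strand_of(pos: int, genes: Sequence[GeneModel]) -> Optional[str]:
    for g in genes:
        s, e = g.span
        if s <= pos < e:
            return g.strand
    return None


def plant_truth(ref: ReferenceBundle, config: SimConfig) -> SyntheticTruth:
    """Plant editing sites, SNPs and artifacts on the generated reference.

    True sites sit only on transcribed-strand adenosines, a configurable
    fraction (default 80%) inside repeat intervals.  Every artifact site
    violates exactly one detection filter by construction, and true sites
    avoid the filter-triggering zones (homopolymer runs, splice-junction
    margins, the duplicated segment) so that planted truth and planted
    artifacts are cleanly separable.
    """
    rng = np.random.default_rng([config.seed, 11])
    (chrom, genome) = next(iter(ref.sequences.items()))
    L = len(genome)
    arr = np.frombuffer(genome.encode(), dtype="S1")
    runs = maximal_run_lengths(genome)

    excluded = np.zeros(L, dtype=bool)
    excluded[runs >= 5] = True
    excluded[:_EDGE_MARGIN] = True
    excluded[-_EDGE_MARGIN:] = True
    for g in ref.gene_models:
        for (s, e) in g.exons:
            excluded[max(0, s - _JUNCTION_MARGIN) : s + _JUNCTION_MARGIN] = True
            excluded[max(0, e - _JUNCTION_MARGIN) : e + _JUNCTION_MARGIN] = True
    (dc, da_s, da_e), (_, db_s, db_e) = ref.extras["duplicated_segment"]
    excluded[max(0, da_s - _EDGE_MARGIN) : da_e + _EDGE_MARGIN] = True
    excluded[max(0, db_s - _EDGE_MARGIN) : db_e + _EDGE_MARGIN] = True

    in_gene = np.zeros(L, dtype=bool)
    sense_a = np.zeros(L, dtype=bool)
    for g in ref.gene_models:
        s, e = g.span
        in_gene[s:e] = True
        want = b"A" if g.strand == "+" else b"T"
        sense_a[s:e] = arr[s:e] == want
    in_repeat = np.zeros(L, dtype=bool)
    for r in ref.repeats:
        in_repeat[r.start : r.end] = True

    eligible = sense_a & in_gene & ~excluded
    in_pool = np.nonzero(eligible & in_repeat)[0]
    out_pool = np.nonzero(eligible & ~in_repeat)[0]

    n = config.n_true_sites
    n_in = int(round(config.repeat_site_fraction * n))
    n_out = n - n_in
    need_out = n_out + config.n_read_end_artifacts
    if len(in_pool) < n_in or len(out_pool) < need_out:
        raise PlacementError(
            f"not enough eligible adenosines: need {n_in} in-repeat "
            f"(have {len(in_pool)}) and {need_out} out-of-repeat "
            f"(have {len(out_pool)})"
        )
    chosen_in = rng.choice(in_pool, size=n_in, replace=False)
    out_take = rng.choice(out_pool, size=need_out, replace=False)
    chosen_out, read_end_pos = out_take[:n_out], out_take[n_out:]
    site_pos = np.sort(np.concatenate([chosen_in, chosen_out]).astype(np.int64))

    stages = config.stages
    offsets = rng.uniform(-config.site_level_spread, config.site_level_spread, n)
    true_sites = []
    for pos, off in zip(site_pos, offsets):
        strand = _strand_of(int(pos), ref.gene_models)
        assert strand is not None
        levels = tuple(
            (stage, float(np.clip(config.stage_levels[stage] + off, 0.0, 1.0)))
            for stage in stages
        )
        true_sites.append(TrueSite(chrom, int(pos), strand, levels))

    used = set(int(p) for p in site_pos) | set(int(p) for p in read_end_pos)

    # heterozygous SNPs anywhere in transcribed regions (any reference base)
    snp_pool = np.nonzero(in_gene & ~excluded)[0]
    snp_pool = np.array([p for p in snp_pool if int(p) not in used], dtype=np.int64)
    if len(snp_pool) < config.n_het_snps:
        raise PlacementError(
            f"not enough positions for {config.n_het_snps} heterozygous SNPs"
        )
    snp_pos = rng.choice(snp_pool, size=config.n_het_snps, replace=False)
    het_snps = []
    for pos in sorted(int(p) for p in snp_pos):
        ref_base = genome[pos]
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[rng.integers(0, 3)]
        strand = _strand_of(pos, ref.gene_models)
        het_snps.append(HetSnp(chrom, pos, ref_base, alt, strand or "+"))
        used.add(pos)

    artifacts: List[ArtifactSite] = []
    for pos in sorted(int(p) for p in read_end_pos):
        strand = _strand_of(pos, ref.gene_models)
        artifacts.append(ArtifactSite(chrom, pos, strand or "+", "read_end"))

    hp_runs = ref.extras["homopolymer_runs"]
    if config.n_homopolymer_artifacts > len(hp_runs):
        raise PlacementError(
            f"requested {config.n_homopolymer_artifacts} homopolymer artifacts "
            f"but only {len(hp_runs)} tracts were planted"
        )
    for (c, s, e, strand) in hp_runs[: config.n_homopolymer_artifacts]:
        pos = (s + e) // 2
        artifacts.append(ArtifactSite(c, pos, strand, "homopolymer"))
        used.add(pos)

    dup_strand = _strand_of(da_s, ref.gene_models) or "+"
    interior = np.arange(da_s + _EDGE_MARGIN, da_e - _EDGE_MARGIN)
    want = b"A" if dup_strand == "+" else b"T"
    dup_as = interior[arr[interior] == want]
    if len(dup_as) < config.n_mismap_artifacts:
        raise PlacementError(
            f"duplicated segment hosts only {len(dup_as)} adenosines for "
            f"{config.n_mismap_artifacts} mismap artifacts"
        )
    mis_pos = rng.choice(dup_as, size=config.n_mismap_artifacts, replace=False)
    for pos in sorted(int(p) for p in mis_pos):
        artifacts.append(ArtifactSite(chrom, pos, dup_strand, "mismap"))
        used.add(pos)

    bg_pool = np.array(
        [p for p in np.nonzero(in_gene & ~excluded)[0] if int(p) not in used],
        dtype=np.int64,
    )
    n_bg = min(config.n_background_sites, len(bg_pool))
    bg_pos = rng.choice(bg_pool, size=n_bg, replace=False) if n_bg else np.array([], int)
    background = [
        (chrom, int(p), _strand_of(int(p), ref.gene_models) or "+")
        for p in sorted(int(x) for x in bg_pos)
    ]

    return SyntheticTruth(
        true_sites=true_sites,
        het_snps=het_snps,
        artifact_sites=artifacts,
        background_positions=background,
        repeat_intervals=list(ref.repeats),
        duplicated_segment=ref.extras["duplicated_segment"],
        stages=stages,
    )


# ---------------------------------------------------------------------------
# WGS genotypes and known SNPs
# ---------------------------------------------------------------------------

def simulate_wgs_genotypes(
    ref: ReferenceBundle, truth: SyntheticTruth, config: SimConfig
) -> List[VcfRecord]:
    """Heterozygous WGS records at planted SNPs; editing sites stay RNA-only.

    Positions without a record are implicitly homozygous-reference.
    """
    return [
        VcfRecord(s.chrom, s.pos, s.ref, (s.alt,), gt="0/1") for s in truth.het_snps
    ]


def known_snp_records(truth: SyntheticTruth) -> List[VcfRecord]:
    """Sites-only catalogue records (dbSNP stand-in) at the planted SNPs."""
    return [VcfRecord(s.chrom, s.pos, s.ref, (s.alt,)) for s in truth.het_snps]


# ---------------------------------------------------------------------------
# RNA evidence
# ---------------------------------------------------------------------------

def _expand_units(
    rng: np.random.Generator,
    config: SimConfig,
    pos: np.ndarray,
    ref_b: np.ndarray,
    alt_b: np.ndarray,
    level: np.ndarray,
    strand: np.ndarray,
    is_read_end: np.ndarray,
) -> pd.DataFrame:
    """Expand per-position units into per-read evidence rows."""
    n_units = len(pos)
    cov = np.maximum(1, rng.poisson(config.coverage_mean, n_units))
    nalt = rng.binomial(cov, level)
    total = int(cov.sum())
    rep = np.repeat(np.arange(n_units), cov)
    within = np.arange(total) - np.repeat(np.cumsum(cov) - cov, cov)
    is_alt = within < np.repeat(nalt, cov)

    base = np.where(is_alt, alt_b[rep], ref_b[rep])
    margin, L = config.read_end_margin, config.read_length
    off5 = rng.integers(margin + 1, L - margin + 1, total)
    re_alt = is_alt & is_read_end[rep]
    if re_alt.any():
        side = rng.integers(0, 2, total)
        near = rng.integers(1, margin + 1, total)
        forced = np.where(side == 0, near, L + 1 - near)
        off5 = np.where(re_alt, forced, off5)
    off3 = L + 1 - off5

    qual = np.full(total, 37, dtype=np.int64)
    err = rng.random(total) < config.base_error_rate
    if err.any():
        idx = np.array([_BASE_INDEX[b] for b in base])
        shift = rng.integers(1, 4, total)
        base = np.where(err, _BASES[(idx + shift) % 4], base)
        qual = np.where(err, rng.integers(10, 31, total), qual)

    return pd.DataFrame(
        {
            "pos": pos[rep],
            "ref_base": ref_b[rep],
            "base": base,
            "qual": qual,
            "off5": off5,
            "off3": off3,
            "strand": strand[rep],
            "_within": within,
        }
    )


def simulate_rna_evidence(
    ref: ReferenceBundle, truth: SyntheticTruth, config: SimConfig
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample site evidence with planted truth and artifacts.

    Returns ``(evidence, realized_levels)`` where ``evidence`` maps sample id
    to an evidence DataFrame and ``realized_levels`` records the per-sample
    realized true editing level of every true site (stage mean plus truncated
    replicate noise) — the quantity the binomial read sampling used.
    """
    (chrom, genome) = next(iter(ref.sequences.items()))

    def sense_pair(strand: str) -> Tuple[str, str]:
        return ("A", "G") if strand == "+" else ("T", "C")

    U1 = "U1"
    t_pos = np.array([s.pos for s in truth.true_sites], dtype=np.int64)
    t_strand = np.array([s.strand for s in truth.true_sites], dtype=U1)
    t_ref = np.array([sense_pair(s.strand)[0] for s in truth.true_sites], dtype=U1)
    t_alt = np.array([sense_pair(s.strand)[1] for s in truth.true_sites], dtype=U1)

    a_pos = np.array([a.pos for a in truth.artifact_sites], dtype=np.int64)
    a_strand = np.array([a.strand for a in truth.artifact_sites], dtype=U1)
    a_ref = np.array([sense_pair(a.strand)[0] for a in truth.artifact_sites], dtype=U1)
    a_alt = np.array([sense_pair(a.strand)[1] for a in truth.artifact_sites], dtype=U1)
    a_read_end = np.array(
        [a.kind == "read_end" for a in truth.artifact_sites], dtype=bool
    )

    s_pos = np.array([s.pos for s in truth.het_snps], dtype=np.int64)
    s_strand = np.array([s.strand for s in truth.het_snps], dtype=U1)
    s_ref = np.array([s.ref for s in truth.het_snps], dtype=U1)
    s_alt = np.array([s.alt for s in truth.het_snps], dtype=U1)

    b_pos = np.array([p for _, p, _ in truth.background_positions], dtype=np.int64)
    b_strand = np.array([st for _, _, st in truth.background_positions], dtype=U1)
    b_ref = np.array([genome[p] for _, p, _ in truth.background_positions], dtype=U1)

    evidence: Dict[str, pd.DataFrame] = {}
    realized: Dict[str, np.ndarray] = {}
    for si, stage in enumerate(truth.stages):
        for r in range(config.n_replicates):
            sample = f"{stage}_r{r + 1}"
            rng = np.random.default_rng(
                [config.seed, 101, si * config.n_replicates + r]
            )
            t_level = np.clip(
                np.array([s.level(stage) for s in truth.true_sites])
                + rng.normal(0.0, config.replicate_sd, len(truth.true_sites)),
                0.0,
                1.0,
            )
            realized[sample] = t_level

            pos = np.concatenate([t_pos, a_pos, s_pos, b_pos])
            ref_b = np.concatenate([t_ref, a_ref, s_ref, b_ref])
            alt_b = np.concatenate([t_alt, a_alt, s_alt, b_ref])
            level = np.concatenate(
                [
                    t_level,
                    np.full(len(a_pos), ARTIFACT_LEVEL),
                    np.full(len(s_pos), 0.5),
                    np.zeros(len(b_pos)),
                ]
            )
            strand = np.concatenate([t_strand, a_strand, s_strand, b_strand])
            is_re = np.concatenate(
                [
                    np.zeros(len(t_pos), bool),
                    a_read_end,
                    np.zeros(len(s_pos), bool),
                    np.zeros(len(b_pos), bool),
                ]
            )
            df = _expand_units(rng, config, pos, ref_b, alt_b, level, strand, is_re)
            df["chrom"] = chrom
            df["sample_id"] = sample
            df["read_id"] = (
                sample
                + "."
                + (df["pos"] + 1).astype(str)
                + "."
                + df["_within"].astype(str)
            )
            df = df.drop(columns="_within")
            df = df.sort_values(["pos", "read_id"], kind="mergesort").reset_index(
                drop=True
            )
            evidence[sample] = df[
                [
                    "chrom", "pos", "ref_base", "sample_id", "read_id",
                    "base", "qual", "off5", "off3", "strand",
                ]
            ]

    levels_df = pd.DataFrame(
        realized, index=[s.key for s in truth.true_sites]
    )
    return evidence, levels_df


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def _sense_window(genome: str, pos: int, strand: str, up: int, down: int) -> str:
    """Transcribed-strand sequence covering sense offsets [-up, +down)."""
    if strand == "+":
        return genome[pos - up : pos + down]
    return revcomp(genome[pos - down + 1 : pos + up + 1])


def _revcomp_rna(seq: str) -> str:
    return revcomp(seq).replace("T", "U")


def simulate_mirnas(
    ref: ReferenceBundle, truth: SyntheticTruth, config: SimConfig
) -> Dict[str, str]:
    """Mature miRNAs engineered against planted 3'-UTR editing sites.

    Cycles through three design classes anchored at 3'-UTR true sites:
    perfect complements of the *edited* flank with the editing position in
    the seed (a binding site gained upon editing), perfect complements of
    the *reference* flank with the site in the seed (lost upon editing), and
    complements pairing the site outside the seed (kept, with changed duplex
    energy).  The class is encoded in the miRNA id.
    """
    (chrom, genome) = next(iter(ref.sequences.items()))
    utr3_sites: List[TrueSite] = []
    for site in truth.true_sites:
        for g in ref.gene_models:
            if any(s <= site.pos < e for (s, e) in g.utr3):
                utr3_sites.append(site)
                break
    mirnas: Dict[str, str] = {}
    if not utr3_sites or config.flank_energy_mirnas == 0:
        return mirnas
    rng = np.random.default_rng([config.seed, 23])
    order = rng.permutation(len(utr3_sites))
    classes = ["gain", "loss", "energy"]
    for k in range(config.flank_energy_mirnas):
        site = utr3_sites[order[k % len(utr3_sites)]]
        klass = classes[k % 3]
        if klass in ("gain", "loss"):
            window = _sense_window(genome, site.pos, site.strand, 18, 4)  # seed pos 4
            idx = 18
        else:
            window = _sense_window(genome, site.pos, site.strand, 10, 12)  # pos 12
            idx = 10
        if klass == "gain":
            window = window[:idx] + "G" + window[idx + 1 :]
        mirnas[f"sim-miR-{k + 1}-{klass}"] = _revcomp_rna(window)
    return mirnas


# ---------------------------------------------------------------------------
# truth I/O (plain TSV)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, sites_path, artifacts_path, snps_path) -> None:
    rows = []
    for s in truth.true_sites:
        row = {"chrom": s.chrom, "pos_1based": s.pos + 1, "strand": s.strand}
        row.update({f"level_{stage}": lvl for stage, lvl in s.levels})
        rows.append(row)
    pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": a.chrom, "pos_1based": a.pos + 1, "strand": a.strand, "kind": a.kind}
            for a in truth.artifact_sites
        ]
    ).to_csv(artifacts_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": s.chrom, "pos_1based": s.pos + 1, "ref": s.ref, "alt": s.alt,
             "strand": s.strand}
            for s in truth.het_snps
        ]
    ).to_csv(snps_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reverse-complement transform (strand-symmetry checks)
# ---------------------------------------------------------------------------

def rc_position(pos: int, length: int) -> int:
    return length - 1 - pos


def reverse_complement_bundle(ref: ReferenceBundle) -> ReferenceBundle:
    """Mirror the whole bundle onto the reverse complement of every contig."""
    lengths = {c: len(s) for c, s in ref.sequences.items()}
    seqs = {c: revcomp(s) for c, s in ref.sequences.items()}
    flip = {"+": "-", "-": "+"}
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            transcript_id=g.transcript_id,
            chrom=g.chrom,
            strand=flip[g.strand],
            exons=sorted(_flip_interval(iv, lengths[g.chrom]) for iv in g.exons),
            cds=sorted(_flip_interval(iv, lengths[g.chrom]) for iv in g.cds),
            biotype=g.biotype,
        )
        for g in ref.gene_models
    ]
    repeats = [
        RepeatInterval(
            r.chrom,
            *_flip_interval((r.start, r.end), lengths[r.chrom]),
            r.family,
            r.subfamily,
            flip[r.strand],
        )
        for r in ref.repeats
    ]
    known = {(c, rc_position(p, lengths[c])) for c, p in ref.known_snps}
    wgs = {
        (c, rc_position(p, lengths[c])): cls for (c, p), cls in ref.wgs_genotypes.items()
    }
    extras = dict(ref.extras)
    if "duplicated_segment" in extras:
        (c1, s1, e1), (c2, s2, e2) = extras["duplicated_segment"]
        extras["duplicated_segment"] = (
            (c1, *_flip_interval((s1, e1), lengths[c1])),
            (c2, *_flip_interval((s2, e2), lengths[c2])),
        )
    if "homopolymer_runs" in extras:
        extras["homopolymer_runs"] = [
            (c, *_flip_interval((s, e), lengths[c]), flip[st])
            for (c, s, e, st) in extras["homopolymer_runs"]
        ]
    return ReferenceBundle(
        sequences=seqs,
        gene_models=genes,
        repeats=repeats,
        known_snps=known,
        wgs_genotypes=wgs,
        multiallelic={(c, rc_position(p, lengths[c])) for c, p in ref.multiallelic},
        extras=extras,
    )


def reverse_complement_evidence(
    df: pd.DataFrame, lengths: Dict[str, int]
) -> pd.DataFrame:
    """Map evidence rows onto the reverse-complemented genome."""
    out = df.copy()
    out["pos"] = out.apply(lambda r: rc_position(r["pos"], lengths[r["chrom"]]), axis=1)
    comp = _COMP
    out["ref_base"] = out["ref_base"].map(comp)
    out["base"] = out["base"].map(comp)
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    out[["off5", "off3"]] = out[["off3", "off5"]].to_numpy()
    return out.sort_values(["pos", "read_id"], kind="mergesort").reset_index(drop=True)
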