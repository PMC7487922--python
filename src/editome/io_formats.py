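"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally.  The on-disk dialects keep
their native conventions: GTF and VCF are 1-based, BED is 0-based half-open,
and the site-evidence TSV records 1-based positions and 1-based offsets from
both read ends.

The site-evidence TSV is the pipeline's primary input: one row per
supporting read per genomic position, with the observed base, its Phred
quality, the read-end offsets and the library strand of the strand-specific
protocol.  In memory it is a :class:`pandas.DataFrame` with columns
``chrom, pos, ref_base, sample_id, read_id, base, qual, off5, off3, strand``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GeneModel",
    "RepeatInterval",
    "ReferenceBundle",
    "EVIDENCE_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_vcf_positions",
    "write_vcf",
    "VcfRecord",
    "read_repeats_bed",
    "read_repeats_out",
    "write_repeats_bed",
    "read_site_evidence",
    "write_site_evidence",
    "read_mirna_fasta",
    "revcomp",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

Interval = Tuple[int, int]


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Parts of intervals ``a`` not covered by intervals ``b`` (both sorted)."""
    out: List[Interval] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class GeneModel:
    """One transcript of one gene, with strand-resolved UTRs.

    ``exons`` and ``cds`` are sorted, non-overlapping, 0-based half-open
    genomic intervals.  For coding transcripts the total CDS length must be
    a multiple of three.  UTRs are derived as exonic minus CDS sequence,
    split by genomic side of the CDS and assigned 5'/3' by strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    cds: List[Interval] = field(default_factory=list)
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exons", self.exons), ("CDS", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise FormatError(
                        f"overlapping {name} in transcript {self.transcript_id}"
                    )
        if self.biotype == "coding":
            if not self.cds:
                raise FormatError(f"coding transcript {self.transcript_id} lacks CDS")
            if self.cds_length % 3 != 0:
                raise FormatError(
                    f"CDS length {self.cds_length} of {self.transcript_id} "
                    "not divisible by 3"
                )
        elif self.cds:
            raise FormatError(
                f"non-coding transcript {self.transcript_id} carries CDS"
            )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> List[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def _utr_parts(self) -> Tuple[List[Interval], List[Interval]]:
        """(left-of-CDS, right-of-CDS) exonic non-CDS parts in genomic order."""
        if not self.cds:
            return [], []
        nc = _subtract(self.exons, self.cds)
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        left = [iv for iv in nc if iv[1] <= cds_lo]
        right = [iv for iv in nc if iv[0] >= cds_hi]
        return left, right

    @property
    def utr5(self) -> List[Interval]:
        left, right = self._utr_parts()
        return left if self.strand == "+" else right

    @property
    def utr3(self) -> List[Interval]:
        left, right = self._utr_parts()
        return right if self.strand == "+" else left


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat-annotation interval, family e.g. ``SINE/tRNA``."""

    chrom: str
    start: int
    end: int
    family: str
    subfamily: str
    strand: str = "+"

    @property
    def name(self) -> str:
        return f"{self.family}:{self.subfamily}"


@dataclass
class ReferenceBundle:
    """Genome, gene models, repeats and DNA variation in one coordinate frame."""

    sequences: Dict[str, str]
    gene_models: List[GeneModel] = field(default_factory=list)
    repeats: List[RepeatInterval] = field(default_factory=list)
    known_snps: Set[Tuple[str, int]] = field(default_factory=set)
    wgs_genotypes: Dict[Tuple[str, int], str] = field(default_factory=dict)
    multiallelic: Set[Tuple[str, int]] = field(default_factory=set)
    extras: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.gene_models:
            L = len(self.sequences[g.chrom])
            if g.span[0] < 0 or g.span[1] > L:
                raise FormatError(f"gene {g.gene_id} outside contig {g.chrom}")
        for r in self.repeats:
            if r.start < 0 or r.end > len(self.sequences[r.chrom]):
                raise FormatError(f"repeat {r.name} outside contig {r.chrom}")

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def genotype(self, chrom: str, pos: int) -> str:
        """WGS genotype class at a position; absent record means hom_ref."""
        return self.wgs_genotypes.get((chrom, pos), "hom_ref")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read FASTA into ``{contig: upper-case sequence}``.

    Duplicate contig names are a format error.
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mirna_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read mature miRNA sequences (RNA alphabet, T folded to U)."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate miRNA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    return out


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_BIOTYPE_TO_INTERNAL = {
    "protein_coding": "coding",
    "coding": "coding",
    "lincRNA": "lincRNA",
    "novel_lncRNA": "novel_lncRNA",
}
_BIOTYPE_TO_GTF = {
    "coding": "protein_coding",
    "lincRNA": "lincRNA",
    "novel_lncRNA": "novel_lncRNA",
}


def read_gtf(path: str | os.PathLike) -> List[GeneModel]:
    """Parse an Ensembl-dialect GTF into :class:`GeneModel` objects.

    GTF's 1-based closed intervals are converted to 0-based half-open.  A
    CDS or exon feature without a ``transcript_id``, or a CDS whose
    transcript has no exon features, is a format error.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc

    exons: Dict[str, List[Interval]] = {}
    cds: Dict[str, List[Interval]] = {}
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    order: List[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise FormatError(f"{path}: {feat.featuretype} without transcript_id")
        tid = tids[0]
        gid = (feat.attributes.get("gene_id") or [tid])[0]
        biotype = (
            feat.attributes.get("gene_biotype")
            or feat.attributes.get("transcript_biotype")
            or ["protein_coding"]
        )[0]
        if tid not in meta:
            meta[tid] = (gid, feat.seqid, feat.strand, biotype)
            order.append(tid)
        iv = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models: List[GeneModel] = []
    for tid in order:
        gid, chrom, strand, raw_biotype = meta[tid]
        if tid not in exons:
            raise FormatError(f"transcript {tid} has CDS but no exon features")
        internal = _BIOTYPE_TO_INTERNAL.get(raw_biotype)
        if internal is None:
            internal = "coding" if tid in cds else "lincRNA"
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                cds=cds.get(tid, []),
                biotype=internal,
            )
        )
    return models


def write_gtf(models: Iterable[GeneModel], path: str | os.PathLike, source: str = "editome") -> None:
    """Write gene models as Ensembl-dialect GTF (gene/transcript/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("#!genome-version synthetic\n")
        for g in models:
            biotype = _BIOTYPE_TO_GTF.get(g.biotype, g.biotype)
            attr_gene = f'gene_id "{g.gene_id}"; gene_biotype "{biotype}";'
            attr_tx = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}"; '
                f'gene_biotype "{biotype}";'
            )
            s, e = g.span
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr_gene}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr_tx}\n"
            )
            for (xs, xe) in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attr_tx}\n"
                )
            # CDS frame accumulates along the transcription direction
            cds = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            for (cs, ce) in cds:
                frame = (3 - consumed % 3) % 3
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{frame}\t{attr_tx}\n"
                )
                consumed += ce - cs


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfRecord:
    """A minimal bi-/multi-allelic VCF record with one optional genotype."""

    chrom: str
    pos: int  # 0-based internally
    ref: str
    alts: Tuple[str, ...]
    gt: Optional[str] = None  # "0/0", "0/1", "1/1" or None for sites-only


_GT_CLASS = {"0/0": "hom_ref", "0/1": "het", "1/0": "het", "1/1": "hom_alt"}


def write_vcf(
    records: Iterable[VcfRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    sample: Optional[str] = None,
) -> None:
    """Write VCF 4.2; genotyped when ``sample`` is given, sites-only otherwise."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=editome\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols += ["FORMAT", sample]
        fh.write("\t".join(cols) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = [r.chrom, str(r.pos + 1), ".", r.ref, ",".join(r.alts), ".", "PASS", "."]
            if sample is not None:
                row += ["GT", r.gt if r.gt is not None else "./."]
            fh.write("\t".join(row) + "\n")


def read_vcf_positions(
    path: str | os.PathLike, mode: str
) -> Tuple[Dict[Tuple[str, int], str] | Set[Tuple[str, int]], Set[Tuple[str, int]]]:
    """Read a VCF in ``genotype`` or ``known_snp`` mode.

    ``genotype`` mode returns ``({(chrom, pos): class}, multiallelic)`` with
    class in ``hom_ref | het | hom_alt``; a missing GT is a format error.
    ``known_snp`` mode returns ``(positions, multiallelic)``.  Records with
    more than two allele types are retained but reported in the
    ``multiallelic`` set so the caller can reject them.
    """
    if mode not in ("genotype", "known_snp"):
        raise ValueError(f"unknown VCF mode {mode!r}")
    import cyvcf2

    multi: Set[Tuple[str, int]] = set()
    if mode == "known_snp":
        positions: Set[Tuple[str, int]] = set()
        vcf = cyvcf2.VCF(str(path))
        for v in vcf:
            key = (v.CHROM, v.POS - 1)
            positions.add(key)
            if len(v.ALT) > 1:
                multi.add(key)
        vcf.close()
        return positions, multi

    genotypes: Dict[Tuple[str, int], str] = {}
    vcf = cyvcf2.VCF(str(path))
    if len(vcf.samples) != 1:
        vcf.close()
        raise FormatError(f"genotype mode expects exactly one sample in {path}")
    for v in vcf:
        key = (v.CHROM, v.POS - 1)
        if len(v.ALT) > 1:
            multi.add(key)
        gt = v.genotypes[0]
        if gt is None or len(gt) < 2 or gt[0] < 0 or gt[1] < 0:
            vcf.close()
            raise FormatError(f"missing GT at {v.CHROM}:{v.POS} in {path}")
        a, b = gt[0], gt[1]
        if a == 0 and b == 0:
            cls = "hom_ref"
        elif a == b:
            cls = "hom_alt"
        else:
            cls = "het"
        genotypes[key] = cls
    vcf.close()
    return genotypes, multi


# ---------------------------------------------------------------------------
# repeats (BED6 and RepeatMasker .out)
# ---------------------------------------------------------------------------

def write_repeats_bed(repeats: Iterable[RepeatInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n"
            )


def _split_repeat_name(name: str) -> Tuple[str, str]:
    family, _, subfamily = name.partition(":")
    return family, subfamily or "unknown"


def read_repeats_bed(path: str | os.PathLike) -> List[RepeatInterval]:
    """Read BED6 repeats; the name column is ``class/family:subfamily``."""
    out: List[RepeatInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: BED needs >= 4 columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5].strip() if len(fields) >= 6 else "+"
            family, subfamily = _split_repeat_name(name)
            out.append(RepeatInterval(chrom, int(start), int(end), family, subfamily, strand))
    return out


def read_repeats_out(path: str | os.PathLike) -> List[RepeatInterval]:
    """Read RepeatMasker ``.out`` annotation (1-based closed query coords)."""
    out: List[RepeatInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header/blank lines
            if len(fields) < 11:
                raise FormatError(f"{path}:{ln}: truncated RepeatMasker line")
            chrom = fields[4]
            start, end = int(fields[5]) - 1, int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            subfamily, family = fields[9], fields[10]
            out.append(RepeatInterval(chrom, start, end, family, subfamily, strand))
    return out


# ---------------------------------------------------------------------------
# site-evidence TSV
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "chrom", "pos", "ref_base", "sample_id", "read_id",
    "base", "qual", "off5", "off3", "strand",
]

_DISK_COLUMNS = [
    "chrom", "pos_1based", "ref_base", "sample_id", "read_id",
    "base", "base_qual_phred", "offset_from_5p", "offset_from_3p", "library_strand",
]

_VALID_BASES = {"A", "C", "G", "T", "N"}


def _validate_evidence(df: pd.DataFrame, origin: str) -> None:
    if len(df) == 0:
        return
    bad = set(df["base"].unique()) - _VALID_BASES
    if bad:
        raise FormatError(f"{origin}: invalid observed base(s) {sorted(bad)}")
    bad = set(df["ref_base"].unique()) - _VALID_BASES
    if bad:
        raise FormatError(f"{origin}: invalid reference base(s) {sorted(bad)}")
    if (df[["off5", "off3"]] < 1).any().any():
        raise FormatError(f"{origin}: read-end offsets must be >= 1")
    if (df["qual"] < 0).any():
        raise FormatError(f"{origin}: base qualities must be >= 0")
    bad = set(df["strand"].unique()) - {"+", "-"}
    if bad:
        raise FormatError(f"{origin}: invalid library strand {sorted(bad)}")


def read_site_evidence(path: str | os.PathLike) -> pd.DataFrame:
    """Read the site-evidence TSV into the internal DataFrame layout."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        dtype={
            "chrom": str, "pos_1based": np.int64, "ref_base": str,
            "sample_id": str, "read_id": str, "base": str,
            "base_qual_phred": np.int64, "offset_from_5p": np.int64,
            "offset_from_3p": np.int64, "library_strand": str,
        },
    )
    missing = [c for c in _DISK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[_DISK_COLUMNS].rename(
        columns={
            "pos_1based": "pos", "base_qual_phred": "qual",
            "offset_from_5p": "off5", "offset_from_3p": "off3",
            "library_strand": "strand",
        }
    )
    df["pos"] = df["pos"] - 1
    _validate_evidence(df, str(path))
    return df.reset_index(drop=True)


def write_site_evidence(df: pd.DataFrame, path: str | os.PathLike) -> None:
    _validate_evidence(df, str(path))
    out = df[EVIDENCE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.columns = _DISK_COLUMNS
    out.to_csv(str(path), sep="\t", index=False)
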