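"""Candidate RNA-DNA difference calling and the five-filter cascade.

Candidates are called from pooled, quality-passing read evidence: a site is
a candidate when exactly two allele types remain after the quality filter
and the minor (non-reference) allele is supported by at least three reads.
Five independent filters then flag likely false positives:

1. genomic variation — heterozygous/non-reference WGS genotypes and
   known-SNP catalogue positions;
2. splice proximity — intronic sites within 4 bp of a splice junction;
3. homopolymers — sites inside maximal single-base runs of >= 5 nt;
4. read ends — alternative-allele reads within 6 bp of either read end are
   discarded, and the site is flagged when fewer than three survive;
5. multi-mapping — sites whose flanking window aligns elsewhere in the
   genome at >= 95% of its self-alignment identity.

Each filter is a pure predicate that only adds flags, so filters commute;
unflagged strand-resolved A-to-G calls are the A-to-I editing sites.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import DetectionConfig
from .io_formats import GeneModel, ReferenceBundle, revcomp
from .synthetic import site_key

__all__ = [
    "DataIntegrityError",
    "VariantCall",
    "EditingSite",
    "MISMATCH_TYPES",
    "call_candidates",
    "filter_genomic_snps",
    "filter_splice_proximal",
    "filter_homopolymer",
    "filter_read_end",
    "filter_multimap",
    "resolve_strand_and_type",
    "apply_filters",
    "select_editing_sites",
    "type_percentages",
]


class DataIntegrityError(ValueError):
    """Evidence disagrees with the reference genome."""


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 12 strand-resolved mismatch types
MISMATCH_TYPES = [
    f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b
]


@dataclass
class VariantCall:
    """A candidate RNA-DNA difference with pooled and per-sample counts."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    sample_counts: Dict[str, Tuple[int, int]]  # sample -> (n_ref, n_alt)
    strand: Optional[str] = None  # transcribed strand, None = unknown
    mismatch_type: Optional[str] = None
    flags: Set[str] = field(default_factory=set)
    n_alt_internal: Optional[int] = None  # alt reads surviving the read-end filter

    @property
    def key(self) -> str:
        return site_key(self.chrom, self.pos, self.strand or ".")


@dataclass
class EditingSite:
    """An accepted A-to-I editing site (A-to-G on the transcribed strand)."""

    chrom: str
    pos: int
    strand: str
    ref_base: str
    alt_base: str
    n_ref: int
    n_alt: int
    sample_counts: Dict[str, Tuple[int, int]]
    annotations: Dict[str, object] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return site_key(self.chrom, self.pos, self.strand)


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

def call_candidates(
    evidence: pd.DataFrame, ref: ReferenceBundle, cfg: DetectionConfig
) -> List[VariantCall]:
    """Call candidate variants from pooled quality-passing reads.

    Reads below ``min_base_qual`` and N calls are ignored.  A position is
    emitted when exactly two allele types remain (one of which must be the
    genomic reference) and the alternative allele is supported by at least
    ``min_alt_reads`` reads pooled across samples.  A mismatch between the
    evidence ``ref_base`` and the genome is a data-integrity error.
    """
    ev = evidence[(evidence["qual"] >= cfg.min_base_qual) & (evidence["base"] != "N")]
    calls: List[VariantCall] = []
    for (chrom, pos), grp in ev.groupby(["chrom", "pos"], sort=True):
        genome_ref = ref.sequences[chrom][pos]
        stated = grp["ref_base"].iloc[0]
        if stated != genome_ref:
            raise DataIntegrityError(
                f"evidence ref_base {stated} != genome {genome_ref} at "
                f"{chrom}:{pos + 1}"
            )
        counts = grp["base"].value_counts()
        alleles = set(counts.index)
        if len(alleles) != 2 or genome_ref not in alleles:
            continue
        alt = next(b for b in alleles if b != genome_ref)
        if int(counts[alt]) < cfg.min_alt_reads:
            continue
        per_sample: Dict[str, Tuple[int, int]] = {}
        for sample, sgrp in grp.groupby("sample_id"):
            sc = sgrp["base"].value_counts()
            per_sample[sample] = (int(sc.get(genome_ref, 0)), int(sc.get(alt, 0)))
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=int(pos),
                ref_base=genome_ref,
                alt_base=alt,
                n_ref=int(counts[genome_ref]),
                n_alt=int(counts[alt]),
                sample_counts=per_sample,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# filters (pure flag-adders; order-independent)
# ---------------------------------------------------------------------------

def filter_genomic_snps(calls: List[VariantCall], ref: ReferenceBundle) -> List[VariantCall]:
    """Flag calls explained by DNA: WGS het/hom-alt genotypes or known SNPs.

    The known-SNP catalogue is matched by position only.  Non-reference
    homozygous WGS genotypes are excluded along with heterozygous ones: a
    hom-alt position is a reference error that would masquerade as 100%
    editing.
    """
    for c in calls:
        gt = ref.genotype(c.chrom, c.pos)
        if gt in ("het", "hom_alt"):
            c.flags.add("wgs_snp")
        if (c.chrom, c.pos) in ref.known_snps:
            c.flags.add("known_snp")
    return calls


def _splice_structures(
    models: Sequence[GeneModel],
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[str, List[Tuple[int, int]]]]:
    starts: Dict[str, List[int]] = {}
    ends: Dict[str, List[int]] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    for g in models:
        for (s, e) in g.exons:
            starts.setdefault(g.chrom, []).append(s)
            ends.setdefault(g.chrom, []).append(e)
            exons.setdefault(g.chrom, []).append((s, e))
    return (
        {c: np.array(sorted(v)) for c, v in starts.items()},
        {c: np.array(sorted(v)) for c, v in ends.items()},
        exons,
    )


def filter_splice_proximal(
    calls: List[VariantCall], models: Sequence[GeneModel], cfg: DetectionConfig
) -> List[VariantCall]:
    """Flag intronic calls within ``splice_window`` bp of a splice junction.

    Exonic positions are never flagged by this filter; the distance of the
    first intronic base next to an exon is 1.
    """
    starts, ends, exons = _splice_structures(models)
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for g in models:
        spans.setdefault(g.chrom, []).append(g.span)
    for c in calls:
        ex = exons.get(c.chrom, [])
        if any(s <= c.pos < e for (s, e) in ex):
            continue  # exonic: out of scope for this filter
        if not any(s <= c.pos < e for (s, e) in spans.get(c.chrom, [])):
            continue  # intergenic
        dist = np.inf
        e_arr = ends.get(c.chrom)
        if e_arr is not None and len(e_arr):
            i = np.searchsorted(e_arr, c.pos, side="right")
            if i > 0:
                dist = min(dist, c.pos - e_arr[i - 1] + 1)
        s_arr = starts.get(c.chrom)
        if s_arr is not None and len(s_arr):
            i = np.searchsorted(s_arr, c.pos, side="right")
            if i < len(s_arr):
                dist = min(dist, s_arr[i] - c.pos)
        if dist <= cfg.splice_window:
            c.flags.add("splice_proximal")
    return calls


def homopolymer_run_length(seq: str, pos: int) -> int:
    """Length of the maximal run of identical bases covering ``pos``."""
    b = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = pos
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def filter_homopolymer(
    calls: List[VariantCall], sequences: Mapping[str, str], cfg: DetectionConfig
) -> List[VariantCall]:
    """Flag calls inside maximal runs of >= ``homopolymer_min_run`` bases."""
    for c in calls:
        if homopolymer_run_length(sequences[c.chrom], c.pos) >= cfg.homopolymer_min_run:
            c.flags.add("homopolymer")
    return calls


def filter_read_end(
    calls: List[VariantCall], evidence: pd.DataFrame, cfg: DetectionConfig
) -> List[VariantCall]:
    """Discard alt reads near either read end; flag calls left short.

    Alternative-allele reads with an offset <= ``read_end_margin`` from the
    5' or the 3' end of their read are removed from the supporting counts;
    the call is flagged when fewer than ``min_alt_reads`` survive.  With a
    margin of 0 the filter is a no-op.
    """
    m = cfg.read_end_margin
    ev = evidence[evidence["qual"] >= cfg.min_base_qual]
    internal = ev[(ev["off5"] > m) & (ev["off3"] > m)]
    counts = internal.groupby(["chrom", "pos", "base"]).size()
    for c in calls:
        n = int(counts.get((c.chrom, c.pos, c.alt_base), 0))
        c.n_alt_internal = n
        if n < cfg.min_alt_reads:
            c.flags.add("read_end")
    return calls


def second_best_identity(
    sequences: Mapping[str, str], chrom: str, pos: int, flank: int
) -> float:
    """Identity of the best *other* genomic locus for the flanking window.

    The window around the call is aligned (semi-global edit distance) to the
    genome with its own locus masked out, and to the reverse complement of
    every contig.  Identity is ``1 - dist/len(window)``; the self-alignment
    identity is 1, so this value is the second-best/best score ratio.
    """
    import edlib

    seq = sequences[chrom]
    s = max(0, pos - flank)
    e = min(len(seq), pos + flank + 1)
    window = seq[s:e]
    best = 0.0
    for name, target in sequences.items():
        if name == chrom:
            target = target[:s] + "N" * (e - s) + target[e:]
        for t in (target, revcomp(target)):
            res = edlib.align(window, t, mode="HW", task="distance")
            d = res["editDistance"]
            if d >= 0:
                best = max(best, 1.0 - d / len(window))
    return best


def filter_multimap(
    calls: List[VariantCall], sequences: Mapping[str, str], cfg: DetectionConfig
) -> List[VariantCall]:
    """Flag calls whose flanking window maps elsewhere almost as well.

    An exhaustive local-alignment uniqueness check: the +/-``multimap_flank``
    window is aligned against the whole genome (both strands, its own locus
    masked) and the call is flagged when the second-best locus reaches
    ``multimap_score_ratio`` of the self-alignment.  Windows at contig ends
    are truncated and still checked.
    """
    for c in calls:
        ratio = second_best_identity(sequences, c.chrom, c.pos, cfg.multimap_flank)
        if ratio >= cfg.multimap_score_ratio:
            c.flags.add("multimap")
    return calls


# ---------------------------------------------------------------------------
# strand and type resolution
# ---------------------------------------------------------------------------

def resolve_strand_and_type(
    calls: List[VariantCall],
    models: Sequence[GeneModel],
    evidence: pd.DataFrame,
) -> List[VariantCall]:
    """Assign the transcribed strand and the strand-resolved mismatch type.

    Inside a single gene the gene strand wins; where genes on both strands
    overlap the strand is unknown and the call is excluded from the type
    tally.  Outside genes the majority library strand of the covering reads
    decides; ties are unknown.  A genomic T>C call on the minus strand is an
    A-to-G mismatch on the transcribed strand.
    """
    spans: Dict[str, List[Tuple[int, int, str]]] = {}
    for g in models:
        s, e = g.span
        spans.setdefault(g.chrom, []).append((s, e, g.strand))
    if len(evidence):
        strand_counts = evidence.groupby(["chrom", "pos"])["strand"].value_counts()
    else:
        strand_counts = pd.Series(dtype=int)
    for c in calls:
        strands = {
            st for (s, e, st) in spans.get(c.chrom, []) if s <= c.pos < e
        }
        if len(strands) == 1:
            c.strand = next(iter(strands))
        elif len(strands) > 1:
            c.strand = None
        else:
            try:
                vc = strand_counts.loc[(c.chrom, c.pos)]
            except KeyError:
                vc = pd.Series(dtype=int)
            plus = int(vc.get("+", 0))
            minus = int(vc.get("-", 0))
            if plus > minus:
                c.strand = "+"
            elif minus > plus:
                c.strand = "-"
            else:
                c.strand = None
        if c.strand == "+":
            c.mismatch_type = f"{c.ref_base}-to-{c.alt_base}"
        elif c.strand == "-":
            c.mismatch_type = f"{_COMP[c.ref_base]}-to-{_COMP[c.alt_base]}"
        else:
            c.mismatch_type = None
    return calls


# ---------------------------------------------------------------------------
# orchestration and selection
# ---------------------------------------------------------------------------

def apply_filters(
    calls: List[VariantCall],
    ref: ReferenceBundle,
    evidence: pd.DataFrame,
    cfg: DetectionConfig,
) -> Tuple[List[VariantCall], Dict[str, int]]:
    """Run the full cascade; returns calls plus per-filter attrition counts."""
    filter_genomic_snps(calls, ref)
    filter_splice_proximal(calls, ref.gene_models, cfg)
    filter_homopolymer(calls, ref.sequences, cfg)
    filter_read_end(calls, evidence, cfg)
    filter_multimap(calls, ref.sequences, cfg)
    resolve_strand_and_type(calls, ref.gene_models, evidence)
    attrition = Counter()
    for c in calls:
        for f in c.flags:
            attrition[f] += 1
    attrition["flagged_total"] = sum(1 for c in calls if c.flags)
    attrition["candidates"] = len(calls)
    attrition["surviving"] = len(calls) - attrition["flagged_total"]
    return calls, dict(attrition)


def type_percentages(counts: Mapping[str, int]) -> Dict[str, float]:
    """Percentage of each mismatch type among strand-resolved calls."""
    total = sum(counts.values())
    if total == 0:
        return {t: 0.0 for t in counts}
    return {t: 100.0 * n / total for t, n in counts.items()}


def select_editing_sites(
    calls: List[VariantCall],
) -> Tuple[List[EditingSite], Dict[str, int], Dict[str, float]]:
    """Split surviving calls into A-to-I sites and the 12-type tally.

    Returns ``(sites, type_counts, type_percentages)`` where the counts run
    over unflagged, strand-resolved calls.  An empty surviving set yields
    empty results (with a warning).
    """
    surviving = [c for c in calls if not c.flags]
    if not surviving:
        import warnings

        warnings.warn("no calls survived the filter cascade", stacklevel=2)
    typed = [c for c in surviving if c.mismatch_type is not None]
    counts = Counter(c.mismatch_type for c in typed)
    pct = type_percentages(counts)
    sites = [
        EditingSite(
            chrom=c.chrom,
            pos=c.pos,
            strand=c.strand,  # type: ignore[arg-type]
            ref_base=c.ref_base,
            alt_base=c.alt_base,
            n_ref=c.n_ref,
            n_alt=c.n_alt,
            sample_counts=dict(c.sample_counts),
        )
        for c in typed
        if c.mismatch_type == "A-to-G"
    ]
    return sites, dict(counts), pct
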