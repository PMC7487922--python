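"""Quantification and characterization of A-to-I editing sites.

The per-site editing level is nG / (nA + nG) over quality-passing reads,
with the A/G axis taken on the transcribed strand (a minus-strand site
counts genomic T as A and genomic C as G).  A level is undefined when the
A+G coverage is below ``min_coverage`` or fewer than ``min_edit_reads``
reads support the edited form.  The per-sample overall editing rate pools
all edited and editable reads across sites with no coverage threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .config import QuantConfig
from .detection import EditingSite
from .io_formats import GeneModel, RepeatInterval
from .synthetic import site_key

__all__ = [
    "FEATURE_PRECEDENCE",
    "RecodingResult",
    "sense_ag_counts",
    "site_editing_level",
    "editing_level_matrix",
    "overall_editing_rate",
    "stage_rates",
    "annotate_feature",
    "annotate_recoding",
    "annotate_repeats",
    "neighbor_preference",
    "rpkm",
]

#: precedence when a site maps to several overlapping transcript features
FEATURE_PRECEDENCE = ["CDS", "3UTR", "5UTR", "ncRNA_exon", "intron", "intergenic"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# levels
# ---------------------------------------------------------------------------

def sense_ag_counts(
    evidence: pd.DataFrame,
    sites: Sequence[EditingSite],
    min_qual: int,
) -> pd.DataFrame:
    """Per (site, sample) counts of sense-strand A and G reads.

    Returns a DataFrame indexed by site key with columns ``(sample, 'nA')``
    and ``(sample, 'nG')`` — zero where a site/sample has no reads.
    """
    if not sites:
        return pd.DataFrame()
    sdf = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "site_strand": [s.strand for s in sites],
            "site": [s.key for s in sites],
        }
    )
    ev = evidence[evidence["qual"] >= min_qual]
    m = ev.merge(sdf, on=["chrom", "pos"], how="inner")
    if len(m) == 0:
        samples = sorted(evidence["sample_id"].unique())
        idx = pd.MultiIndex.from_product([samples, ["nA", "nG"]])
        return pd.DataFrame(0, index=sdf["site"], columns=idx)
    sense = np.where(
        m["site_strand"] == "+", m["base"], m["base"].map(_COMP)
    )
    m = m.assign(sense=sense)
    m = m[m["sense"].isin(["A", "G"])]
    tab = (
        m.groupby(["site", "sample_id", "sense"]).size().unstack(
            ["sample_id", "sense"], fill_value=0
        )
    )
    tab = tab.reindex(sdf["site"], fill_value=0)
    tab.columns = pd.MultiIndex.from_tuples(
        [(s, {"A": "nA", "G": "nG"}[b]) for s, b in tab.columns]
    )
    samples = sorted(evidence["sample_id"].unique())
    full = pd.MultiIndex.from_product([samples, ["nA", "nG"]])
    return tab.reindex(columns=full, fill_value=0)


def site_editing_level(
    evidence: pd.DataFrame, site: EditingSite, qcfg: QuantConfig | None = None
) -> Dict[str, Optional[float]]:
    """Per-sample editing level nG / (nA + nG) of one A-to-I site.

    Undefined (``None``) when A+G coverage is below ``min_coverage`` or
    fewer than ``min_edit_reads`` G reads support the editing form.
    """
    qcfg = qcfg or QuantConfig()
    tab = sense_ag_counts(evidence, [site], qcfg.min_qual)
    out: Dict[str, Optional[float]] = {}
    for sample in tab.columns.get_level_values(0).unique():
        nA = int(tab.loc[site.key, (sample, "nA")])
        nG = int(tab.loc[site.key, (sample, "nG")])
        if nA + nG < qcfg.min_coverage or nG < qcfg.min_edit_reads:
            out[sample] = None
        else:
            out[sample] = nG / (nA + nG)
    return out


def editing_level_matrix(
    evidence: pd.DataFrame,
    sites: Sequence[EditingSite],
    qcfg: QuantConfig | None = None,
) -> pd.DataFrame:
    """Site x sample matrix of editing levels (NaN where undefined)."""
    qcfg = qcfg or QuantConfig()
    tab = sense_ag_counts(evidence, sites, qcfg.min_qual)
    if tab.empty:
        return pd.DataFrame()
    samples = tab.columns.get_level_values(0).unique()
    out = {}
    for sample in samples:
        nA = tab[(sample, "nA")].to_numpy(float)
        nG = tab[(sample, "nG")].to_numpy(float)
        cov = nA + nG
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = nG / cov
        lvl[(cov < qcfg.min_coverage) | (nG < qcfg.min_edit_reads)] = np.nan
        out[sample] = lvl
    return pd.DataFrame(out, index=tab.index)


def overall_editing_rate(
    evidence: pd.DataFrame,
    sites: Sequence[EditingSite],
    min_qual: int = 25,
) -> pd.Series:
    """Per-sample overall editing rate: sum nG / sum (nA + nG) over all sites.

    No per-site coverage criterion is applied — every identified A-to-I
    position contributes all of its quality-passing A and G reads.  A sample
    with a zero denominator is NaN (with a warning).
    """
    if not sites:
        raise ValueError("overall editing rate needs at least one A-to-I site")
    tab = sense_ag_counts(evidence, sites, min_qual)
    samples = tab.columns.get_level_values(0).unique()
    out = {}
    for sample in samples:
        nG = float(tab[(sample, "nG")].sum())
        denom = nG + float(tab[(sample, "nA")].sum())
        if denom == 0:
            import warnings

            warnings.warn(f"sample {sample}: no A/G reads at any site", stacklevel=2)
            out[sample] = np.nan
        else:
            out[sample] = nG / denom
    return pd.Series(out).sort_index()


def stage_rates(per_sample: pd.Series, design: Mapping[str, str]) -> pd.Series:
    """Per-stage rate = unweighted mean of the replicate values."""
    stages = pd.Series({s: design[s] for s in per_sample.index})
    return per_sample.groupby(stages).mean()


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _feature_trees(models: Sequence[GeneModel]) -> Dict[str, Dict[str, IntervalTree]]:
    trees: Dict[str, Dict[str, IntervalTree]] = {}

    def tree(chrom: str, kind: str) -> IntervalTree:
        return trees.setdefault(chrom, {}).setdefault(kind, IntervalTree())

    for g in models:
        if g.biotype == "coding":
            for s, e in g.cds:
                tree(g.chrom, "CDS").addi(s, e, g.gene_id)
            for s, e in g.utr3:
                tree(g.chrom, "3UTR").addi(s, e, g.gene_id)
            for s, e in g.utr5:
                tree(g.chrom, "5UTR").addi(s, e, g.gene_id)
        else:
            for s, e in g.exons:
                tree(g.chrom, "ncRNA_exon").addi(s, e, g.gene_id)
        s, e = g.span
        tree(g.chrom, "gene").addi(s, e, g.gene_id)
    return trees


def annotate_feature(
    site: EditingSite | Tuple[str, int],
    models: Sequence[GeneModel],
    trees: Optional[Dict[str, Dict[str, IntervalTree]]] = None,
) -> Tuple[str, List[str]]:
    """Assign one genomic feature to a site, with host gene ids.

    Precedence across overlapping transcripts:
    CDS > 3'-UTR > 5'-UTR > ncRNA exon > intron > intergenic.
    """
    chrom, pos = (site.chrom, site.pos) if isinstance(site, EditingSite) else site
    trees = trees if trees is not None else _feature_trees(models)
    per_chrom = trees.get(chrom, {})
    for kind in ("CDS", "3UTR", "5UTR", "ncRNA_exon"):
        t = per_chrom.get(kind)
        if t:
            hits = t[pos]
            if hits:
                return kind, sorted({h.data for h in hits})
    t = per_chrom.get("gene")
    if t:
        hits = t[pos]
        if hits:
            return "intron", sorted({h.data for h in hits})
    return "intergenic", []


@dataclass(frozen=True)
class RecodingResult:
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str

    @property
    def synonymous(self) -> bool:
        return self.aa_ref == self.aa_alt


def annotate_recoding(
    site: EditingSite,
    models: Sequence[GeneModel],
    sequences: Mapping[str, str],
) -> RecodingResult:
    """Translate the reference and A->G-edited codon of a CDS site.

    The codon is built on the transcribed strand from the spliced CDS; the
    edited base becomes G at the site.  Raises ``ValueError`` when the site
    is not inside the CDS of any coding transcript of matching strand.
    """
    from .io_formats import revcomp as _rc

    for g in models:
        if g.biotype != "coding" or g.chrom != site.chrom or g.strand != site.strand:
            continue
        if not any(s <= site.pos < e for (s, e) in g.cds):
            continue
        if g.strand == "+":
            pieces = [(s, e) for (s, e) in g.cds]
            offset = 0
            for s, e in pieces:
                if s <= site.pos < e:
                    offset += site.pos - s
                    break
                offset += e - s
            cds_seq = "".join(sequences[g.chrom][s:e] for s, e in pieces)
        else:
            pieces = [(s, e) for (s, e) in reversed(g.cds)]
            offset = 0
            for s, e in pieces:
                if s <= site.pos < e:
                    offset += e - 1 - site.pos
                    break
                offset += e - s
            cds_seq = "".join(_rc(sequences[g.chrom][s:e]) for s, e in pieces)
        if len(cds_seq) % 3 != 0:
            raise ValueError(f"CDS phase inconsistent for {g.transcript_id}")
        ci = offset // 3
        codon = cds_seq[3 * ci : 3 * ci + 3]
        within = offset % 3
        if codon[within] != "A":
            raise ValueError(
                f"site {site.key} is not an adenosine on the coding strand"
            )
        edited = codon[:within] + "G" + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(edited).translate())
        return RecodingResult(codon, edited, aa_ref, aa_alt)
    raise ValueError(f"site {site.key} is not in a CDS of a same-strand transcript")


def annotate_repeats(
    sites: Sequence[EditingSite], repeats: Sequence[RepeatInterval]
) -> Tuple[List[str], pd.Series, pd.Series]:
    """Label sites with their repeat family and tabulate the distribution.

    Returns ``(labels, family_counts, subfamily_counts)``; a site outside
    every repeat is labelled ``none``.
    """
    trees: Dict[str, IntervalTree] = {}
    for r in repeats:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    labels: List[str] = []
    for s in sites:
        hits = trees.get(s.chrom, IntervalTree())[s.pos]
        labels.append(next(iter(hits)).data.name if hits else "none")
    fam = pd.Series(
        [lb.split(":")[0] if lb != "none" else "none" for lb in labels]
    ).value_counts()
    sub = pd.Series(
        [lb.split(":", 1)[1] if lb != "none" else "none" for lb in labels]
    ).value_counts()
    return labels, fam, sub


def neighbor_preference(
    sites: Sequence[EditingSite], sequences: Mapping[str, str]
) -> pd.DataFrame:
    """Base frequencies at -1/+1 of the edited A on the edited strand.

    Returns a 4 x 2 table (rows A/C/G/T, columns ``-1``/``+1``), each column
    summing to 1.  Sites at a contig edge are skipped for the affected
    column.
    """
    counts = {c: {b: 0 for b in "ACGT"} for c in ("-1", "+1")}
    for s in sites:
        seq = sequences[s.chrom]
        if s.strand == "+":
            up = seq[s.pos - 1] if s.pos >= 1 else None
            down = seq[s.pos + 1] if s.pos + 1 < len(seq) else None
        else:
            up = _COMP[seq[s.pos + 1]] if s.pos + 1 < len(seq) else None
            down = _COMP[seq[s.pos - 1]] if s.pos >= 1 else None
        if up in counts["-1"]:
            counts["-1"][up] += 1
        if down in counts["+1"]:
            counts["+1"][down] += 1
    df = pd.DataFrame(counts).reindex(list("ACGT"))
    return df / df.sum(axis=0)


def rpkm(read_count: float, exon_model_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length_bp <= 0:
        raise ValueError("exon model length must be > 0")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    return read_count / (exon_model_length_bp / 1000.0) / (total_mapped_reads / 1e6)
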