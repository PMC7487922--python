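"""miRNA target prediction on reference vs A-to-I-edited 3'-UTR flanks.

A Miranda-style scanner: the miRNA (reversed, so the duplex is antiparallel)
is locally aligned against the target with complementarity scoring —
Watson-Crick match +5, G:U wobble +1, mismatch -3, affine gaps -9/-4,
substitution scores doubled in the seed (miRNA positions 2-8 from the 5'
end).  Duplex stability uses a simplified RNA/RNA nearest-neighbor model:
a constant per stack class (G:C/G:C -3.3, mixed -2.1, A:U/A:U -1.1,
G:U-containing -0.5 kcal/mol) plus +4.1 per interior unpaired stretch.
The model is deterministic and monotone — adequate for classifying which
miRNA-target pairs are gained, lost or energy-shifted by an A->G edit.

Targets are handled in the DNA alphabet and miRNAs in RNA; U and T pair
interchangeably.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import MirnaParams
from .detection import EditingSite
from .io_formats import GeneModel, revcomp

__all__ = [
    "FlankPair",
    "AlignmentColumn",
    "MirnaTargetHit",
    "PairEffect",
    "extract_flank_pair",
    "scan_targets",
    "duplex_energy",
    "classify_effects",
    "site_effects",
    "compare_energy_distributions",
]

_WATSON_CRICK = {("A", "U"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("T", "G")}

_STACK_GC = -3.3
_STACK_AU = -1.1
_STACK_MIXED = -2.1
_STACK_GU = -0.5
_LOOP_PENALTY = 4.1


@dataclass(frozen=True)
class FlankPair:
    """Reference and edited flank of one 3'-UTR site, transcribed-strand."""

    site: str
    strand: str
    ref_seq: str
    edit_seq: str
    center: int  # index of the edited base within the flanks
    trunc_left: int  # bases missing on the 5' side (contig edge)
    trunc_right: int

    def __post_init__(self) -> None:
        diffs = [
            i for i, (a, b) in enumerate(zip(self.ref_seq, self.edit_seq)) if a != b
        ]
        if diffs != [self.center]:
            raise ValueError("flank pair must differ exactly at the edited position")


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a target/miRNA duplex alignment.

    ``m_pos`` is the 1-based miRNA position from the 5' end; gap columns
    leave one side None.  ``kind`` is match | wobble | mismatch | gap.
    """

    t_idx: Optional[int]
    m_pos: Optional[int]
    t_base: Optional[str]
    m_base: Optional[str]
    kind: str

    @property
    def paired(self) -> bool:
        return self.kind in ("match", "wobble")


@dataclass(frozen=True)
class MirnaTargetHit:
    mirna: str
    target_start: int
    target_end: int  # half-open on the scanned sequence
    score: float
    energy: float
    columns: Tuple[AlignmentColumn, ...]

    def covers(self, index: int) -> bool:
        return self.target_start <= index < self.target_end


@dataclass(frozen=True)
class PairEffect:
    site: str
    mirna: str
    classification: str  # gained | lost | energy_changed | unchanged
    e_ref: Optional[float]
    e_edit: Optional[float]

    @property
    def delta_e(self) -> Optional[float]:
        if self.e_ref is None or self.e_edit is None:
            return None
        return self.e_edit - self.e_ref


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------

def extract_flank_pair(
    site: EditingSite,
    sequences: Mapping[str, str],
    models: Sequence[GeneModel],
    flank: int = 50,
    require_utr3: bool = True,
) -> FlankPair:
    """Extract +/-``flank`` bp around a 3'-UTR site on the transcribed strand.

    The edited sequence substitutes A->G at the site.  Flanks truncated at
    contig edges are recorded.  A site outside every same-strand 3'-UTR is
    a scope error unless ``require_utr3`` is disabled.
    """
    if require_utr3:
        in_utr3 = any(
            g.chrom == site.chrom
            and g.strand == site.strand
            and any(s <= site.pos < e for (s, e) in g.utr3)
            for g in models
        )
        if not in_utr3:
            raise ValueError(f"site {site.key} is not in a 3'-UTR")
    seq = sequences[site.chrom]
    s = max(0, site.pos - flank)
    e = min(len(seq), site.pos + flank + 1)
    window = seq[s:e]
    if site.strand == "+":
        center = site.pos - s
        trunc_left = flank - (site.pos - s)
        trunc_right = flank - (e - 1 - site.pos)
    else:
        window = revcomp(window)
        center = e - 1 - site.pos
        trunc_left = flank - (e - 1 - site.pos)
        trunc_right = flank - (site.pos - s)
    if window[center] != "A":
        raise ValueError(f"site {site.key}: transcribed-strand base is not A")
    edited = window[:center] + "G" + window[center + 1 :]
    return FlankPair(
        site=site.key,
        strand=site.strand,
        ref_seq=window,
        edit_seq=edited,
        center=center,
        trunc_left=trunc_left,
        trunc_right=trunc_right,
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _pair_kind(t_base: str, m_base: str) -> str:
    if (t_base, m_base) in _WATSON_CRICK:
        return "match"
    if (t_base, m_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _align_one(target: str, guide: str, params: MirnaParams) -> Optional[MirnaTargetHit]:
    """Best local (Gotoh) alignment of the reversed miRNA against the target.

    Ties in score keep the leftmost target position.  Returns a hit
    regardless of thresholds; the caller applies them.
    """
    n, m = len(target), len(guide)
    if n == 0 or m == 0:
        return None
    grev = guide[::-1]  # column j pairs miRNA 1-based position m - j + 1
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in miRNA (target base unpaired)
    F = np.full((n + 1, m + 1), NEG)  # gap in target
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 open from H, 0 extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.int8)

    def sub_score(i: int, j: int) -> Tuple[float, str]:
        t_base, m_base = target[i - 1], grev[j - 1]
        kind = _pair_kind(t_base, m_base)
        base = {
            "match": params.match,
            "wobble": params.wobble,
            "mismatch": params.mismatch,
        }[kind]
        m_pos = m - j + 1
        if params.seed_start <= m_pos <= params.seed_end:
            base *= params.seed_scale
        return base, kind

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1][j] + params.gap_open
            e_ext = E[i - 1][j] + params.gap_extend
            if e_open >= e_ext:
                E[i][j], ptr_e[i][j] = e_open, 1
            else:
                E[i][j], ptr_e[i][j] = e_ext, 0
            f_open = H[i][j - 1] + params.gap_open
            f_ext = F[i][j - 1] + params.gap_extend
            if f_open >= f_ext:
                F[i][j], ptr_f[i][j] = f_open, 1
            else:
                F[i][j], ptr_f[i][j] = f_ext, 0
            s, _ = sub_score(i, j)
            diag = H[i - 1][j - 1] + s
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            H[i][j], ptr_h[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j

    if best <= 0:
        return None
    cols: List[AlignmentColumn] = []
    i, j, state = bi, bj, "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptr_h[i][j]
            if p == 0:
                break
            if p == 1:
                _, kind = sub_score(i, j)
                cols.append(
                    AlignmentColumn(i - 1, m - j + 1, target[i - 1], grev[j - 1], kind)
                )
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append(AlignmentColumn(i - 1, None, target[i - 1], None, "gap"))
            if ptr_e[i][j] == 1:
                state = "H"
            i -= 1
        else:
            cols.append(AlignmentColumn(None, m - j + 1, None, grev[j - 1], "gap"))
            if ptr_f[i][j] == 1:
                state = "H"
            j -= 1
    cols.reverse()
    t_idx = [c.t_idx for c in cols if c.t_idx is not None]
    hit = MirnaTargetHit(
        mirna="",
        target_start=min(t_idx),
        target_end=max(t_idx) + 1,
        score=float(best),
        energy=0.0,
        columns=tuple(cols),
    )
    return hit


def duplex_energy(columns: Sequence[AlignmentColumn]) -> Optional[float]:
    """Nearest-neighbor duplex energy of an alignment, in kcal/mol.

    Sums one constant per stack of consecutive paired columns (classed by
    the two base pairs) and adds a loop penalty per interior unpaired
    stretch.  A duplex with no paired position is undefined (None); a
    single base pair has no stacks and energy 0.
    """
    paired_idx = [k for k, c in enumerate(columns) if c.paired]
    if not paired_idx:
        return None

    def pair_class(c: AlignmentColumn) -> str:
        if c.kind == "wobble":
            return "GU"
        return "GC" if c.t_base in ("G", "C") else "AU"

    energy = 0.0
    for k, k2 in zip(paired_idx, paired_idx[1:]):
        if k2 == k + 1:  # consecutive duplex stack
            a, b = pair_class(columns[k]), pair_class(columns[k2])
            if "GU" in (a, b):
                energy += _STACK_GU
            elif a == "GC" and b == "GC":
                energy += _STACK_GC
            elif a == "AU" and b == "AU":
                energy += _STACK_AU
            else:
                energy += _STACK_MIXED
        else:  # interior unpaired stretch (loop or bulge)
            energy += _LOOP_PENALTY
    return energy


def scan_targets(
    seq: str, mirnas: Mapping[str, str], params: MirnaParams | None = None
) -> List[MirnaTargetHit]:
    """Scan a target sequence with each miRNA; report thresholded best hits.

    One best-scoring hit per miRNA (ties broken leftmost); a hit is
    reported when its score reaches ``score_threshold`` and its duplex
    energy is at most ``energy_threshold``.
    """
    params = params or MirnaParams()
    hits: List[MirnaTargetHit] = []
    for mid in sorted(mirnas):
        guide = mirnas[mid].upper().replace("T", "U")
        raw = _align_one(seq.upper(), guide, params)
        if raw is None or raw.score < params.score_threshold:
            continue
        energy = duplex_energy(raw.columns)
        if energy is None or energy > params.energy_threshold:
            continue
        hits.append(
            MirnaTargetHit(
                mirna=mid,
                target_start=raw.target_start,
                target_end=raw.target_end,
                score=raw.score,
                energy=energy,
                columns=raw.columns,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

def classify_effects(
    site: str,
    ref_hits: Sequence[MirnaTargetHit],
    edit_hits: Sequence[MirnaTargetHit],
) -> List[PairEffect]:
    """Classify each miRNA's ref-vs-edited hit pattern for one site.

    gained: hit only on the edited flank; lost: only on the reference;
    energy_changed: hit on both with a changed duplex energy; unchanged
    otherwise.
    """
    ref_by = {h.mirna: h for h in ref_hits}
    edit_by = {h.mirna: h for h in edit_hits}
    out: List[PairEffect] = []
    for mid in sorted(set(ref_by) | set(edit_by)):
        r, e = ref_by.get(mid), edit_by.get(mid)
        if r is None and e is not None:
            cls, er, ee = "gained", None, e.energy
        elif r is not None and e is None:
            cls, er, ee = "lost", r.energy, None
        else:
            assert r is not None and e is not None
            er, ee = r.energy, e.energy
            cls = "energy_changed" if er != ee else "unchanged"
        out.append(PairEffect(site, mid, cls, er, ee))
    return out


def site_effects(
    pair: FlankPair, mirnas: Mapping[str, str], params: MirnaParams | None = None
) -> Tuple[List[MirnaTargetHit], List[MirnaTargetHit], List[PairEffect]]:
    """Scan both flanks of one site and classify the per-miRNA effects."""
    params = params or MirnaParams()
    ref_hits = scan_targets(pair.ref_seq, mirnas, params)
    edit_hits = scan_targets(pair.edit_seq, mirnas, params)
    return ref_hits, edit_hits, classify_effects(pair.site, ref_hits, edit_hits)


def summarize_effects(effects: Iterable[PairEffect]) -> Dict[str, Dict[str, int]]:
    """Counts of miRNA-target pairs and distinct sites per effect class."""
    pairs: Dict[str, int] = {}
    sites: Dict[str, set] = {}
    for e in effects:
        pairs[e.classification] = pairs.get(e.classification, 0) + 1
        sites.setdefault(e.classification, set()).add(e.site)
    return {
        "pairs": pairs,
        "sites": {k: len(v) for k, v in sites.items()},
    }


def compare_energy_distributions(
    energies_ref: Sequence[float], energies_edit: Sequence[float]
) -> Dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of duplex-energy samples.

    Reports the statistic, p-value, group medians and the edit-minus-ref
    median difference.  Fully tied samples give p = 1.
    """
    a = np.asarray(energies_ref, float)
    b = np.asarray(energies_edit, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 energies per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        stat, p = 0.0, 1.0
    else:
        res = stats.ranksums(b, a)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "pvalue": p,
        "median_ref": float(np.median(a)),
        "median_edit": float(np.median(b)),
        "median_diff": float(np.median(b) - np.median(a)),
    }
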