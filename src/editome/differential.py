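"""Differential editing between stages, sample clustering and enrichment.

Differentially edited sites (DESs) are called per pairwise comparison with
a two-sided Student's t-test on per-replicate editing levels, Benjamini-
Hochberg FDR across the tested sites of the comparison, and the joint
cutoff FDR <= 0.05 and |delta| >= 0.1, where delta = mean(B) - mean(A) for
comparison "B-A" (positive delta = up-regulated editing in the later
stage).  Sites need at least two defined levels per group to be tested;
ineligible sites are excluded from the BH denominator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .config import DiffConfig

__all__ = [
    "bh_fdr",
    "test_des",
    "summarize_comparisons",
    "cluster_samples",
    "ClusterResult",
    "overlap_genes",
    "enrichment_test",
]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped to <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_des(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    comparison: str | None = None,
    cfg: DiffConfig | None = None,
) -> pd.DataFrame:
    """Call DESs between two sample groups of an editing-level matrix.

    ``matrix`` is sites x samples with NaN for undefined levels.  Returns
    one row per *tested* site with columns ``site, comparison, mean_a,
    mean_b, delta, t, p, q, direction, is_des``.  Sites with fewer than two
    defined values in either group are skipped entirely.  When both groups
    have zero variance and equal means the test is uninformative and p = 1.
    """
    cfg = cfg or DiffConfig()
    comparison = comparison or "B-A"
    a = matrix[list(group_a)].to_numpy(float)
    b = matrix[list(group_b)].to_numpy(float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    eligible = (n_a >= cfg.min_defined_per_group) & (n_b >= cfg.min_defined_per_group)

    rows = []
    for i in np.nonzero(eligible)[0]:
        va = a[i][~np.isnan(a[i])]
        vb = b[i][~np.isnan(b[i])]
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        delta = mean_b - mean_a
        if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
            if mean_a == mean_b:
                t, p = 0.0, 1.0
            else:
                t = np.inf if delta > 0 else -np.inf
                p = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = stats.ttest_ind(vb, va, equal_var=cfg.equal_var)
            t, p = float(t), float(p)
        rows.append(
            {
                "site": matrix.index[i],
                "comparison": comparison,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "delta": delta,
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["site", "comparison", "mean_a", "mean_b", "delta", "t", "p"],
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.array([])
    out["direction"] = np.where(out["delta"] > 0, "up", "down")
    out["is_des"] = (out["q"] <= cfg.max_fdr) & (out["delta"].abs() >= cfg.min_delta)
    return out


def summarize_comparisons(
    des_frames: Mapping[str, pd.DataFrame],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-comparison up/down/total counts plus union and full intersection.

    The union counts each distinct DES site once across comparisons; the
    intersection is the set of sites called in *every* comparison.
    """
    rows = []
    des_sets: List[Set] = []
    for name, df in des_frames.items():
        des = df[df["is_des"]]
        up = int((des["direction"] == "up").sum())
        down = int((des["direction"] == "down").sum())
        rows.append(
            {"comparison": name, "up": up, "down": down, "total": up + down}
        )
        des_sets.append(set(des["site"]))
    union = set().union(*des_sets) if des_sets else set()
    inter = set.intersection(*des_sets) if des_sets else set()
    summary = pd.DataFrame(rows, columns=["comparison", "up", "down", "total"])
    return summary, {"union": len(union), "shared_by_all": len(inter)}


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: List[str]
    leaf_order: List[str]
    newick: str


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def cluster_samples(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster samples by their editing-level profiles.

    Distance is 1 - Pearson correlation over the sites defined in *all*
    samples; linkage is average (UPGMA).  Samples are ordered by name
    before clustering so the result is invariant to input column order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    mat = matrix[sorted(matrix.columns)].dropna(axis=0, how="any")
    if len(mat) < 2:
        raise ValueError(
            f"only {len(mat)} sites are defined in all samples; need >= 2"
        )
    labels = list(mat.columns)
    corr = np.corrcoef(mat.to_numpy(float).T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(
        linkage=linkage,
        labels=labels,
        leaf_order=[labels[i] for i in order],
        newick=_to_newick(linkage, labels),
    )


def overlap_genes(des_genes: Iterable[str], deg_list: Iterable[str]) -> Set[str]:
    """Genes both differentially edited and differentially expressed."""
    return set(des_genes) & set(deg_list)


def enrichment_test(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``p = P(X >= k)`` with k the overlap between ``gene_set`` and the term,
    drawn from a universe of size N with K term genes and n set genes.
    Term genes outside the universe are pruned (with a warning).  Adjusted
    q-values are Benjamini-Hochberg across terms.
    """
    uni = set(universe)
    genes = set(gene_set)
    if not genes <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for term, members in term_to_genes.items():
        members = set(members)
        outside = members - uni
        if outside:
            warnings.warn(
                f"term {term}: {len(outside)} gene(s) outside the universe pruned",
                stacklevel=2,
            )
            members &= uni
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(genes)))
        rows.append(
            {"term": term, "overlap": k, "term_size": len(members),
             "set_size": len(genes), "universe": len(uni), "p": min(p, 1.0)}
        )
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "set_size", "universe", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.array([])
    return out
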