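"""Differential-expression integration: up/down calling, directional set
overlaps, and distance-bracket peak-gene hypergeometric association.

DE calls follow the count-tool convention: a gene is "up" when its adjusted
p-value is below alpha and its fold change exceeds the threshold (default
adjusted p < 0.01, fold > 1.6); "down" is the mirrored criterion; all other
genes are "unchanged".

The distance-bracket association asks, for each distance d in a ladder of
nested windows (0..d), whether a gene set overlaps the genes whose TSS lies
within d bp of a peak centre more often than expected by hypergeometric
chance over the tested-gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, Peak, distance_to_nearest


def call_de(
    stats_table: pd.DataFrame,
    fold_change: float = 1.6,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Label each gene up / down / unchanged from fold change and adjusted p.

    Requires ``gene_id``, ``log2_fold_change`` and ``adjusted_p`` columns;
    a missing adjusted_p is an error (never silently fall back to raw p).
    """
    for col in ("gene_id", "log2_fold_change", "adjusted_p"):
        if col not in stats_table.columns:
            raise ValueError(f"missing required column {col!r}")
    df = stats_table.copy()
    lfc = df["log2_fold_change"].to_numpy(dtype=float)
    padj = df["adjusted_p"].to_numpy(dtype=float)
    log2_thresh = np.log2(fold_change)
    sig = padj < alpha
    df["label"] = np.select(
        [sig & (lfc > log2_thresh), sig & (-lfc > log2_thresh)],
        ["up", "down"],
        default="unchanged",
    )
    return df


def de_sets(de_table: pd.DataFrame) -> tuple[set[str], set[str], set[str]]:
    """(up, down, universe) gene-id sets from a labelled DE table."""
    up = set(de_table.loc[de_table["label"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["label"] == "down", "gene_id"])
    return up, down, set(de_table["gene_id"])


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) drawing n from N with K successes."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def set_overlap_test(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> tuple[int, float, float]:
    """Overlap of two gene sets with Fisher exact (two-sided) and
    hypergeometric upper-tail p over a shared universe."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(set_a & set_b)
    n_a, n_b, N = len(set_a), len(set_b), len(universe)
    table = [[k, n_a - k], [n_b - k, N - n_a - n_b + k]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return k, float(fisher_p), hypergeom_upper_tail(k, N, n_a, n_b)


@dataclass
class BracketAssociation:
    brackets: list[int]
    table: pd.DataFrame  # columns: bracket, k, K, n, N, p, neglog10_p


def genes_near_peaks(
    peaks: Sequence[Peak],
    universe: Sequence[GeneModel],
    bracket: int,
) -> set[str]:
    """Universe gene ids whose TSS is within ``bracket`` bp of a peak centre."""
    points = [(g.chrom, g.tss) for g in universe]
    dists = distance_to_nearest(points, [(p.chrom, p.centre) for p in peaks])
    return {g.gene_id for g, d in zip(universe, dists)
            if not np.isnan(d) and d <= bracket}


def distance_bracket_association(
    peaks: Sequence[Peak],
    gene_set: set[str],
    universe: Sequence[GeneModel],
    brackets: Sequence[int],
    cluster_filter: tuple[Mapping[str, int], int] | None = None,
    mode: str = "cumulative",
) -> BracketAssociation:
    """Hypergeometric association of a gene set with peak-proximal genes at
    nested distance brackets.

    ``cluster_filter=(labels, c)`` restricts the peaks to those whose id
    maps to cluster ``c``.  ``mode="ring"`` tests disjoint distance rings
    instead of nested windows.
    """
    if list(brackets) != sorted(set(brackets)):
        raise ValueError("brackets must be strictly increasing")
    if not universe:
        raise ValueError("empty gene universe")
    universe_ids = {g.gene_id for g in universe}
    if not gene_set <= universe_ids:
        raise ValueError("gene_set must be a subset of the universe")
    if cluster_filter is not None:
        labels, want = cluster_filter
        peaks = [p for i, p in enumerate(peaks)
                 if labels.get(p.name or f"peak_{i}") == want]

    N, n = len(universe_ids), len(gene_set)
    rows = []
    prev: set[str] = set()
    for d in brackets:
        near = genes_near_peaks(peaks, universe, d) if peaks else set()
        ring = near - prev if mode == "ring" else near
        if mode == "ring":
            prev = near
        K = len(ring)
        k = len(gene_set & ring)
        p = hypergeom_upper_tail(k, N, K, n) if K > 0 else 1.0
        rows.append((d, k, K, n, N, p, -np.log10(p) if p > 0 else np.inf))
    table = pd.DataFrame(rows, columns=["bracket", "k", "K", "n", "N", "p",
                                        "neglog10_p"])
    return BracketAssociation(brackets=list(brackets), table=table)


def random_gene_control(
    peaks: Sequence[Peak],
    n_genes: int,
    universe: Sequence[GeneModel],
    brackets: Sequence[int],
    n_sets: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (and sd) per-bracket overlap count of seeded random gene sets of
    size ``n_genes`` drawn without replacement from the universe."""
    if n_genes > len(universe):
        raise ValueError("n_genes exceeds universe size")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted({g.gene_id for g in universe}))
    near_by_bracket = {d: genes_near_peaks(peaks, universe, d) for d in brackets}
    counts = np.zeros((n_sets, len(brackets)))
    for s in range(n_sets):
        draw = set(rng.choice(ids, size=n_genes, replace=False))
        for j, d in enumerate(brackets):
            counts[s, j] = len(draw & near_by_bracket[d])
    return pd.DataFrame({
        "bracket": list(brackets),
        "mean_overlap": counts.mean(axis=0),
        "sd_overlap": counts.std(axis=0, ddof=1) if n_sets > 1 else 0.0,
    })


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
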