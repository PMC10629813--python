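"""TAD-scoped regional regulation analyses.

Peaks (by centre) and genes (by TSS) are assigned to non-overlapping TADs
with half-open containment.  On top of that assignment the module computes:
the up/down proportion of DE genes in TADs grouped by the peak clusters
they contain (Fisher exact vs the no-peak TADs); a permutation test of
up-gene / peak co-localisation within TADs; peak-to-boundary distances
against random control points; and the adjacent-TAD distance-mirror
control, which searches the opposite direction from each peak for gene
TSSs at a similar distance (default +/-25%) landing in a different TAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, Peak, TAD, validate_tads

UNDEFINED = math.nan


@dataclass
class TADAssignment:
    tad_peaks: dict[str, list[str]]    # tad_id -> peak ids (centre inside)
    tad_genes: dict[str, list[str]]    # tad_id -> gene ids (TSS inside)
    peak_tad: dict[str, str]           # peak id -> tad id
    gene_tad: dict[str, str]           # gene id -> tad id
    unassigned_peaks: list[str]
    unassigned_genes: list[str]


def assign_to_tads(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tads: Sequence[TAD],
) -> TADAssignment:
    """Assign peak centres and gene TSSs to TADs by half-open containment."""
    validate_tads(tads)
    by_chrom: dict[str, list[TAD]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    index: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        index[chrom] = (np.array([t.start for t in ts]),
                        np.array([t.end for t in ts]),
                        [t.tad_id for t in ts])

    def locate(chrom: str, pos: int) -> str | None:
        if chrom not in index:
            return None
        starts, ends, ids = index[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return ids[i]
        return None

    asn = TADAssignment({t.tad_id: [] for t in tads},
                        {t.tad_id: [] for t in tads}, {}, {}, [], [])
    for i, p in enumerate(peaks):
        pid = p.name or f"peak_{i}"
        tid = locate(p.chrom, p.centre)
        if tid is None:
            asn.unassigned_peaks.append(pid)
        else:
            asn.tad_peaks[tid].append(pid)
            asn.peak_tad[pid] = tid
    for g in genes:
        tid = locate(g.chrom, g.tss)
        if tid is None:
            asn.unassigned_genes.append(g.gene_id)
        else:
            asn.tad_genes[tid].append(g.gene_id)
            asn.gene_tad[g.gene_id] = tid
    return asn


def tad_categories(
    assignment: TADAssignment,
    cluster_of_peak: Mapping[str, int],
    exclusive: bool = False,
) -> dict[object, set[str]]:
    """TAD ids per category: ``1..k`` (contains >= 1 peak of that cluster)
    and ``"no_peak"``.  By default a TAD with peaks from several clusters
    counts in each such category; ``exclusive=True`` drops multi-cluster
    TADs from the cluster categories."""
    clusters = sorted(set(cluster_of_peak.values()))
    cats: dict[object, set[str]] = {c: set() for c in clusters}
    cats["no_peak"] = set()
    for tid, pids in assignment.tad_peaks.items():
        present = {cluster_of_peak[p] for p in pids if p in cluster_of_peak}
        if not present:
            cats["no_peak"].add(tid)
        elif exclusive and len(present) > 1:
            continue
        else:
            for c in present:
                cats[c].add(tid)
    return cats


def tad_direction_proportions(
    assignment: TADAssignment,
    cluster_of_peak: Mapping[str, int],
    up: set[str],
    down: set[str],
    exclusive: bool = False,
) -> pd.DataFrame:
    """Up/down DE-gene counts per TAD category with Fisher exact p vs the
    no-peak category.

    The statistical unit is the gene (genes in multi-gene TADs are not
    collapsed), which overstates independence when regulation is regional;
    interpret p-values accordingly.
    """
    if up & down:
        raise ValueError("up and down gene sets must be disjoint")
    cats = tad_categories(assignment, cluster_of_peak, exclusive=exclusive)

    def counts(tids: set[str]) -> tuple[int, int]:
        genes = {g for t in tids for g in assignment.tad_genes[t]}
        return len(genes & up), len(genes & down)

    ref_up, ref_down = counts(cats["no_peak"])
    rows = []
    for cat in [c for c in cats if c != "no_peak"] + ["no_peak"]:
        u, d = counts(cats[cat])
        prop = u / (u + d) if (u + d) else UNDEFINED
        if cat == "no_peak" or not cats["no_peak"]:
            p = UNDEFINED
        else:
            _, p = stats.fisher_exact([[u, d], [ref_up, ref_down]],
                                      alternative="two-sided")
        rows.append((str(cat), len(cats[cat]), u, d, prop, p))
    return pd.DataFrame(rows, columns=["category", "n_tads", "up", "down",
                                       "prop_up", "fisher_p"])


def colocalization_permutation_test(
    up_genes: set[str],
    peaks: Sequence[Peak],
    assignment: TADAssignment,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed fraction of up-genes sharing a TAD with >= 1 peak, and an
    empirical p from permuting gene labels over all assigned genes.

    The permutation keeps the genes-per-TAD structure fixed and uses the
    add-one estimator p = (1 + #{null >= obs}) / (1 + n_perm), which never
    returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    peak_tads = {tid for tid, pids in assignment.tad_peaks.items() if pids}
    all_genes = np.array(sorted(assignment.gene_tad))
    in_peak_tad = np.array([assignment.gene_tad[g] in peak_tads
                            for g in all_genes])
    up_assigned = [g for g in all_genes if g in up_genes]
    n_up = len(up_assigned)
    if n_up == 0 or not peaks:
        return 0.0, 1.0
    observed = sum(assignment.gene_tad[g] in peak_tads for g in up_assigned) / n_up

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        draw = rng.choice(len(all_genes), size=n_up, replace=False)
        if in_peak_tad[draw].mean() >= observed:
            ge += 1
    return float(observed), (1 + ge) / (1 + n_perm)


def boundary_distance(peak: Peak, tad: TAD) -> int:
    """bp from peak centre to the nearer TAD boundary (<= half the length)."""
    c = peak.centre
    return min(c - tad.start, tad.end - c)


def sample_tad_positions(tads: Sequence[TAD], n: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Uniform positions within TAD-covered territory; returns distances to
    the nearer boundary of the containing TAD."""
    lengths = np.array([t.length for t in tads], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(tads), size=n, p=probs)
    out = np.empty(n)
    for i, j in enumerate(idx):
        t = tads[j]
        u = rng.integers(t.start, t.end)
        out[i] = min(u - t.start, t.end - u)
    return out


def boundary_distance_test(
    peaks_by_cluster: Mapping[int, Sequence[Peak]],
    tads: Sequence[TAD],
    n_control: int = 2360,
    n_control_sets: int = 2,
    seed: int = 0,
) -> tuple[dict[int, np.ndarray], list[np.ndarray], pd.DataFrame]:
    """Peak-to-boundary distances per cluster vs random control points.

    Controls are uniform positions within TAD territory (``n_control``
    each, ``n_control_sets`` independent sets).  Welch's two-sided t-test
    compares each cluster with each control set; clusters with fewer than
    two assigned peaks get an undefined-sentinel p.  Peaks outside all TADs
    are excluded (their count is retrievable from the distance lengths).
    """
    validate_tads(tads)
    by_chrom: dict[str, list[TAD]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t.start)

    def containing(p: Peak) -> TAD | None:
        for t in by_chrom.get(p.chrom, []):
            if t.start <= p.centre < t.end:
                return t
        return None

    dists: dict[int, np.ndarray] = {}
    for c, peaks in peaks_by_cluster.items():
        vals = [boundary_distance(p, t) for p in peaks
                if (t := containing(p)) is not None]
        dists[c] = np.array(vals, dtype=float)

    rng = np.random.default_rng(seed)
    controls = [sample_tad_positions(tads, n_control, rng)
                for _ in range(n_control_sets)]

    rows = []
    for c in sorted(dists):
        for s, ctrl in enumerate(controls):
            if len(dists[c]) < 2:
                p = UNDEFINED
            else:
                _, p = stats.ttest_ind(dists[c], ctrl, equal_var=False)
            rows.append((c, s, len(dists[c]),
                         dists[c].mean() if len(dists[c]) else UNDEFINED,
                         ctrl.mean(), p))
    table = pd.DataFrame(rows, columns=["cluster", "control_set", "n_peaks",
                                        "mean_distance", "control_mean", "t_p"])
    return dists, controls, table


@dataclass
class MirrorControlResult:
    n_qualifying_peaks: int
    n_candidate_genes: int
    n_up_candidates: int


def adjacent_tad_mirror(
    peaks: Sequence[Peak],
    up_genes: set[str],
    genes: Sequence[GeneModel],
    tads: Sequence[TAD],
    assignment: TADAssignment,
    tolerance: float = 0.25,
    strict_adjacent: bool = False,
) -> MirrorControlResult:
    """Distance-mirror control for regional regulation.

    For every (peak, up-gene) pair sharing a TAD, take the peak-centre to
    TSS distance d and search the opposite direction for gene TSSs at a
    similar distance (within ``tolerance``) that reside in a TAD different
    from the peak's ("adjacent" = any other TAD by default;
    ``strict_adjacent`` restricts to the immediately flanking TADs).
    Returns the number of peaks with >= 1 candidate, the number of unique
    candidate genes, and how many of those candidates are themselves
    up-regulated.
    """
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must be in (0, 1)")
    gene_by_id = {g.gene_id: g for g in genes}
    tad_by_id = {t.tad_id: t for t in tads}
    sorted_tads: dict[str, list[TAD]] = {}
    for t in tads:
        sorted_tads.setdefault(t.chrom, []).append(t)
    for chrom in sorted_tads:
        sorted_tads[chrom].sort(key=lambda t: t.start)

    def flanking_ids(tid: str) -> set[str]:
        t = tad_by_id[tid]
        row = sorted_tads[t.chrom]
        i = row.index(t)
        out = set()
        if i > 0:
            out.add(row[i - 1].tad_id)
        if i + 1 < len(row):
            out.add(row[i + 1].tad_id)
        return out

    qualifying_peaks: set[str] = set()
    candidates: set[str] = set()
    for i, peak in enumerate(peaks):
        pid = peak.name or f"peak_{i}"
        tid = assignment.peak_tad.get(pid)
        if tid is None:
            continue
        partner_up = [g for g in assignment.tad_genes[tid] if g in up_genes]
        if not partner_up:
            continue
        allowed = flanking_ids(tid) if strict_adjacent else None
        c = peak.centre
        for gid in partner_up:
            d = abs(gene_by_id[gid].tss - c)
            if d == 0:
                continue
            s = 1 if gene_by_id[gid].tss > c else -1
            lo, hi = (1 - tolerance) * d, (1 + tolerance) * d
            for cand in genes:
                if cand.chrom != peak.chrom:
                    continue
                dprime = (c - cand.tss) * s  # positive on the opposite side
                if not (lo <= dprime <= hi):
                    continue
                cand_tid = assignment.gene_tad.get(cand.gene_id)
                if cand_tid is None or cand_tid == tid:
                    continue
                if allowed is not None and cand_tid not in allowed:
                    continue
                qualifying_peaks.add(pid)
                candidates.add(cand.gene_id)
    return MirrorControlResult(
        n_qualifying_peaks=len(qualifying_peaks),
        n_candidate_genes=len(candidates),
        n_up_candidates=len(candidates & up_genes),
    )
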