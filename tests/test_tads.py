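"""TAD assignment, regional direction test, co-localization permutation,
boundary distances, and the adjacent-TAD mirror control."""

import math

import numpy as np
import pytest

from tadreg.intervals import GeneModel, Peak, TAD
from tadreg.tads import (adjacent_tad_mirror, assign_to_tads,
                         boundary_distance, boundary_distance_test,
                         colocalization_permutation_test,
                         sample_tad_positions, tad_direction_proportions)


def tads_three():
    return [TAD("chr1", 0, 100_000, tad_id="A"),
            TAD("chr1", 100_000, 200_000, tad_id="B"),
            TAD("chr1", 250_000, 350_000, tad_id="C")]  # gap before C


def gene(pos, gid, strand="+"):
    if strand == "+":
        return GeneModel("chr1", pos, pos + 1_000, strand="+", gene_id=gid)
    return GeneModel("chr1", pos - 999, pos + 1, strand="-", gene_id=gid)


# --- assign_to_tads --------------------------------------------------------

def test_half_open_containment_boundaries():
    tads = tads_three()
    genes = [gene(100_000, "at_start"),          # TSS exactly at B's start
             gene(200_000, "at_end")]            # TSS exactly at B's end
    asn = assign_to_tads([], genes, tads)
    assert asn.gene_tad["at_start"] == "B"
    assert "at_end" in asn.unassigned_genes      # gap between B and C


def test_peak_in_gap_unassigned():
    peak = Peak("chr1", 210_000, 210_400, name="p")
    asn = assign_to_tads([peak], [], tads_three())
    assert asn.unassigned_peaks == ["p"]


def test_assignment_partitions_totals():
    rng = np.random.default_rng(6)
    tads = tads_three()
    peaks = [Peak("chr1", int(s), int(s) + 400, name=f"p{i}")
             for i, s in enumerate(rng.integers(0, 400_000, size=50))]
    genes = [gene(int(p), f"g{i}")
             for i, p in enumerate(rng.integers(0, 400_000, size=80))]
    asn = assign_to_tads(peaks, genes, tads)
    assert sum(len(v) for v in asn.tad_peaks.values()) + \
        len(asn.unassigned_peaks) == len(peaks)
    assert sum(len(v) for v in asn.tad_genes.values()) + \
        len(asn.unassigned_genes) == len(genes)


# --- tad_direction_proportions --------------------------------------------

def build_direction_fixture(cat_counts, nopeak_counts):
    """One TAD per category with the requested (up, down) gene counts."""
    tads, genes, peaks = [], [], []
    up, down = set(), set()
    pos = 0

    def fill(tid, n_up, n_down, with_peak):
        nonlocal pos
        tads.append(TAD("chr1", pos, pos + 100_000, tad_id=tid))
        if with_peak:
            peaks.append(Peak("chr1", pos + 50_000, pos + 50_400,
                              name=f"pk_{tid}"))
        for i in range(n_up + n_down):
            gid = f"{tid}_g{i}"
            genes.append(gene(pos + 1_000 + i * 10, gid))
            (up if i < n_up else down).add(gid)
        pos += 100_000

    fill("T1", *cat_counts, True)
    fill("T0", *nopeak_counts, False)
    asn = assign_to_tads(peaks, genes, tads)
    clusters = {p.name: 1 for p in peaks}
    return asn, clusters, up, down


def test_direction_identical_counts_no_signal():
    asn, clusters, up, down = build_direction_fixture((5, 5), (5, 5))
    tab = tad_direction_proportions(asn, clusters, up, down)
    r1 = tab[tab.category == "1"].iloc[0]
    assert r1.prop_up == pytest.approx(0.5)
    assert r1.fisher_p == pytest.approx(1.0)


def test_direction_exact_fisher_hand_case():
    # category (3 up, 0 down) vs no-peak (0 up, 3 down): p = 0.1
    asn, clusters, up, down = build_direction_fixture((3, 0), (0, 3))
    tab = tad_direction_proportions(asn, clusters, up, down)
    r1 = tab[tab.category == "1"].iloc[0]
    assert r1.fisher_p == pytest.approx(0.1)


def test_direction_no_de_genes_sentinel():
    asn, clusters, _, _ = build_direction_fixture((0, 0), (0, 0))
    tab = tad_direction_proportions(asn, clusters, set(), set())
    assert math.isnan(tab[tab.category == "1"].iloc[0].prop_up)


def test_direction_overlapping_updown_errors():
    asn, clusters, up, down = build_direction_fixture((2, 2), (2, 2))
    with pytest.raises(ValueError):
        tad_direction_proportions(asn, clusters, up, up)


def test_multi_cluster_tad_counts_in_each_category():
    tads = [TAD("chr1", 0, 100_000, tad_id="T")]
    peaks = [Peak("chr1", 10_000, 10_400, name="a"),
             Peak("chr1", 60_000, 60_400, name="b")]
    genes = [gene(5_000, "g0")]
    asn = assign_to_tads(peaks, genes, tads)
    tab = tad_direction_proportions(asn, {"a": 1, "b": 2}, {"g0"}, set())
    assert tab[tab.category == "1"].iloc[0].up == 1
    assert tab[tab.category == "2"].iloc[0].up == 1


# --- colocalization permutation test ---------------------------------------

def test_permutation_no_peaks():
    asn, clusters, up, down = build_direction_fixture((3, 3), (3, 3))
    obs, p = colocalization_permutation_test(up, [],
        assign_to_tads([], [gene(1_000, g) for g in up | down],
                       [TAD("chr1", 0, 100_000, tad_id="A")]))
    assert (obs, p) == (0.0, 1.0)


def test_permutation_all_genes_up_p_one():
    asn, clusters, up, down = build_direction_fixture((4, 0), (0, 0))
    peaks = [Peak("chr1", 50_000, 50_400, name="pk_T1")]
    obs, p = colocalization_permutation_test(up, peaks, asn, n_perm=200,
                                             seed=0)
    assert p == 1.0


def test_permutation_planted_enrichment():
    # all up-genes in the peak TAD, many other genes elsewhere
    tads = [TAD("chr1", 0, 100_000, tad_id="P"),
            TAD("chr1", 100_000, 200_000, tad_id="Q")]
    peaks = [Peak("chr1", 50_000, 50_400, name="pk")]
    genes = [gene(1_000 + i * 10, f"up{i}") for i in range(10)]
    genes += [gene(101_000 + i * 10, f"bg{i}") for i in range(40)]
    asn = assign_to_tads(peaks, genes, tads)
    up = {f"up{i}" for i in range(10)}
    obs, p = colocalization_permutation_test(up, peaks, asn, n_perm=1000,
                                             seed=1)
    assert obs == 1.0
    assert p <= 0.01


def test_permutation_p_positive_and_deterministic():
    asn, clusters, up, down = build_direction_fixture((3, 3), (3, 3))
    peaks = [Peak("chr1", 50_000, 50_400, name="pk_T1")]
    r1 = colocalization_permutation_test(up, peaks, asn, n_perm=500, seed=3)
    r2 = colocalization_permutation_test(up, peaks, asn, n_perm=500, seed=3)
    assert r1 == r2
    assert 0 < r1[1] <= 1


# --- boundary distances ----------------------------------------------------

def test_boundary_distance_cases():
    tad = TAD("chr1", 100_000, 200_000, tad_id="T")
    mid = Peak("chr1", 149_800, 150_200)      # centre 150000, L/2 = 50000
    assert boundary_distance(mid, tad) == 50_000
    at_edge = Peak("chr1", 100_000, 100_400)  # centre 100200
    assert boundary_distance(at_edge, tad) == 200
    assert boundary_distance(Peak("chr1", 99_900, 100_101), tad) == 0


def test_boundary_distance_at_most_half_length():
    rng = np.random.default_rng(12)
    tad = TAD("chr1", 0, 100_000, tad_id="T")
    for s in rng.integers(0, 99_000, size=50):
        p = Peak("chr1", int(s), int(s) + 500)
        assert boundary_distance(p, tad) <= tad.length / 2


def test_uniform_positions_mean_quarter_length():
    # min(U, L - U) for U uniform on (0, L) is uniform on (0, L/2): mean L/4
    L = 100_000
    tads = [TAD("chr1", 0, L, tad_id="T")]
    rng = np.random.default_rng(0)
    d = sample_tad_positions(tads, 2360, rng)
    se = (L / 2) / math.sqrt(12) / math.sqrt(len(d))
    assert abs(d.mean() - L / 4) <= 3 * se


def test_boundary_test_table_and_sentinel():
    tads = tads_three()
    by_cluster = {1: [Peak("chr1", 50_000, 50_400, name="a"),
                      Peak("chr1", 150_000, 150_400, name="b")],
                  2: [Peak("chr1", 10_000, 10_400, name="c")]}  # < 2 peaks
    dists, controls, table = boundary_distance_test(by_cluster, tads,
                                                    n_control=100, seed=0)
    assert len(controls) == 2
    assert set(table["cluster"]) == {1, 2}
    assert table[table.cluster == 2]["t_p"].isna().all()
    assert not table[table.cluster == 1]["t_p"].isna().any()


# --- adjacent_tad_mirror ---------------------------------------------------

def mirror_fixture(candidate_up=False):
    # TAD B [0, 120k), TAD A [120k, 250k): peak at 170k, partner TSS 220k
    # (d = 50k, opposite direction window [107.5k, 132.5k] intersect B)
    tads = [TAD("chr1", 0, 120_000, tad_id="B"),
            TAD("chr1", 120_000, 250_000, tad_id="A")]
    peaks = [Peak("chr1", 169_800, 170_200, name="pk")]  # centre 170000
    genes = [gene(220_000, "partner"), gene(115_000, "cand")]
    up = {"partner"} | ({"cand"} if candidate_up else set())
    asn = assign_to_tads(peaks, genes, tads)
    return peaks, up, genes, tads, asn


def test_mirror_hand_geometry():
    peaks, up, genes, tads, asn = mirror_fixture(candidate_up=False)
    res = adjacent_tad_mirror(peaks, up, genes, tads, asn)
    assert (res.n_qualifying_peaks, res.n_candidate_genes,
            res.n_up_candidates) == (1, 1, 0)
    res_up = adjacent_tad_mirror(*mirror_fixture(candidate_up=True)[:5])
    assert (res_up.n_qualifying_peaks, res_up.n_candidate_genes,
            res_up.n_up_candidates) == (1, 1, 1)


def test_mirror_empty_when_no_shared_tad():
    tads = tads_three()
    peaks = [Peak("chr1", 50_000, 50_400, name="pk")]
    genes = [gene(150_000, "far_up")]
    asn = assign_to_tads(peaks, genes, tads)
    res = adjacent_tad_mirror(peaks, {"far_up"}, genes, tads, asn)
    assert (res.n_qualifying_peaks, res.n_candidate_genes,
            res.n_up_candidates) == (0, 0, 0)


def test_mirror_candidate_in_own_tad_excluded():
    # candidate TSS in the peak's own TAD must not count
    tads = [TAD("chr1", 0, 300_000, tad_id="A"),
            TAD("chr1", 300_000, 400_000, tad_id="B")]
    peaks = [Peak("chr1", 149_800, 150_200, name="pk")]  # centre 150000
    genes = [gene(200_000, "partner"),   # d = 50000, same TAD
             gene(100_000, "own_tad")]   # mirrored position, but TAD A
    asn = assign_to_tads(peaks, genes, tads)
    res = adjacent_tad_mirror(peaks, {"partner"}, genes, tads, asn)
    assert res.n_candidate_genes == 0


def test_mirror_tolerance_bounds():
    peaks, up, genes, tads, asn = mirror_fixture()
    with pytest.raises(ValueError):
        adjacent_tad_mirror(peaks, up, genes, tads, asn, tolerance=0)
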