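"""Summit classification, genomic distribution, repeat composition and
IUPAC consensus scanning (against a regex oracle)."""

import re

import numpy as np
import pytest

from tadreg.annotation import (CATEGORIES, IUPAC, classify_summit,
                               consensus_scan, genome_baseline,
                               genomic_distribution, iupac_regex,
                               random_background_regions,
                               repeat_composition,
                               reverse_complement_motif)
from tadreg.intervals import GeneModel, GenomicInterval, Peak, RepeatElement


def peak_at(pos, chrom="chr1"):
    return Peak(chrom, pos - 50, pos + 50, summit=pos)


class DictSequences:
    """Sequence provider over literal per-region strings."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = seqs

    def fetch(self, chrom, start, end):
        s = self.seqs[chrom]
        start = max(0, start)
        return s[start:end]


# --- classify_summit -------------------------------------------------------

def test_promoter_window_plus_strand():
    gene = GeneModel("chr1", 10_000, 30_000, strand="+", gene_id="g")
    assert classify_summit(peak_at(9_500), [gene]) == "promoter"
    assert classify_summit(peak_at(10_100), [gene]) == "promoter"
    assert classify_summit(peak_at(8_999), [gene]) == "distal_intergenic"


def test_promoter_window_minus_strand_mirrored():
    # gene [20000, 30000): TSS = 29999, promoter window [29899, 30999]
    gene = GeneModel("chr1", 20_000, 30_000, strand="-", gene_id="g")
    assert classify_summit(peak_at(30_500), [gene]) == "promoter"
    assert classify_summit(peak_at(29_899), [gene]) == "promoter"
    assert classify_summit(peak_at(31_000), [gene]) == "distal_intergenic"


def test_tts_window_plus_strand():
    gene = GeneModel("chr1", 10_000, 30_000, strand="+", gene_id="g")
    # TTS = 29999, window [29899, 30999]
    assert classify_summit(peak_at(30_500), [gene]) == "tts"


def test_no_genes_on_chromosome_is_distal():
    gene = GeneModel("chr2", 0, 10_000, strand="+", gene_id="g")
    assert classify_summit(peak_at(5_000, "chr1"), [gene]) == "distal_intergenic"


def test_interior_exon_intron_split():
    exons = (GenomicInterval("chr1", 10_000, 12_000),
             GenomicInterval("chr1", 20_000, 22_000))
    gene = GeneModel("chr1", 10_000, 30_000, strand="+", gene_id="g",
                     exons=exons)
    assert classify_summit(peak_at(11_500), [gene]) == "exonic"
    assert classify_summit(peak_at(15_000), [gene]) == "intronic"


def test_exonless_gene_interior_is_exonic():
    gene = GeneModel("chr1", 10_000, 30_000, strand="+", gene_id="g")
    assert classify_summit(peak_at(15_000), [gene]) == "exonic"


def test_promoter_precedence_over_interior():
    # a promoter of gene b inside the body of gene a
    a = GeneModel("chr1", 10_000, 50_000, strand="+", gene_id="a")
    b = GeneModel("chr1", 30_000, 40_000, strand="+", gene_id="b")
    assert classify_summit(peak_at(29_500), [a, b]) == "promoter"


def test_strand_flip_symmetry():
    """Mirroring genes and summits about a midpoint preserves categories."""
    rng = np.random.default_rng(11)
    L = 1_000_000
    genes = []
    for i in range(20):
        start = int(rng.integers(0, L - 30_000))
        length = int(rng.integers(5_000, 30_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel("chr1", start, start + length,
                               strand=strand, gene_id=f"g{i}"))
    flipped = [GeneModel("chr1", L - g.end, L - g.start,
                         strand=("-" if g.strand == "+" else "+"),
                         gene_id=g.gene_id) for g in genes]
    for pos in rng.integers(1_000, L - 1_000, size=120):
        pos = int(pos)
        got = classify_summit(peak_at(pos), genes)
        mirrored = classify_summit(peak_at(L - 1 - pos), flipped)
        assert got == mirrored, f"pos {pos}: {got} != {mirrored}"


# --- genomic_distribution --------------------------------------------------

def test_distribution_constructed_fixture():
    gene = GeneModel("chr1", 100_000, 130_000, strand="+", gene_id="g")
    peaks = [peak_at(99_500 + i) for i in range(3)]          # promoters
    peaks += [peak_at(500_000 + 1_000 * i) for i in range(7)]  # intergenic
    dist = genomic_distribution(peaks, [gene])
    assert dist["promoter"] == pytest.approx(0.3)
    assert dist["distal_intergenic"] == pytest.approx(0.7)
    assert sum(dist.values()) == pytest.approx(1.0)


def test_distribution_empty_peaks_errors():
    with pytest.raises(ValueError):
        genomic_distribution([], [])


def test_distribution_sums_to_one_random():
    rng = np.random.default_rng(5)
    genes = [GeneModel("chr1", int(s), int(s) + 8_000, strand="+",
                       gene_id=f"g{i}")
             for i, s in enumerate(rng.integers(0, 900_000, size=15))]
    peaks = [peak_at(int(p)) for p in rng.integers(1_000, 999_000, size=60)]
    dist = genomic_distribution(peaks, genes)
    assert sum(dist.values()) == pytest.approx(1.0)
    assert set(dist) == set(CATEGORIES)


def test_genome_baseline_single_gene_bp_fractions():
    # plus-strand gene [10000, 30000) on a 100 kb chromosome
    gene = GeneModel("chr1", 10_000, 30_000, strand="+", gene_id="g")
    base = genome_baseline([gene], {"chr1": 100_000})
    assert base["promoter"] == pytest.approx(1_101 / 100_000)  # [9000, 10100]
    assert base["tts"] == pytest.approx(1_101 / 100_000)       # [29899, 30999]
    # interior [10101, 29899 - 1 + 1) -> [10101, 29899): exonless => exonic
    assert base["exonic"] == pytest.approx((29_899 - 10_101) / 100_000)
    assert base["intronic"] == 0.0
    assert sum(base.values()) == pytest.approx(1.0)


# --- repeat_composition ----------------------------------------------------

def repeat(chrom, start, end, cls, fam, name="r"):
    return RepeatElement(chrom, start, end, strand="+", repeat_name=name,
                         repeat_class=cls, repeat_family=fam)


def test_no_repeats_all_zero():
    comp = repeat_composition({1: [peak_at(100)]}, [])
    assert all(v == 0 for v in comp.fractions[1].values())


def test_every_peak_covered_fraction_one():
    peaks = [peak_at(1_000), peak_at(5_000)]
    reps = [repeat("chr1", 0, 10_000, "LTR", "ERV1")]
    comp = repeat_composition({1: peaks}, reps)
    assert comp.fractions[1]["LTR"] == 1.0


def test_class_and_family_fixture():
    # 4 peaks: 2 overlap ERV1, 1 overlaps ERVL, 1 none
    peaks = [peak_at(1_000), peak_at(5_000), peak_at(9_000), peak_at(20_000)]
    reps = [repeat("chr1", 900, 1_100, "LTR", "ERV1", "a"),
            repeat("chr1", 4_900, 5_100, "LTR", "ERV1", "b"),
            repeat("chr1", 8_900, 9_100, "LTR", "ERVL", "c")]
    comp = repeat_composition({1: peaks}, reps, level="class")
    assert comp.fractions[1]["LTR"] == pytest.approx(0.75)
    fam = repeat_composition({1: peaks}, reps, level="family",
                             parent_class="LTR")
    assert fam.fractions[1]["ERV1"] == pytest.approx(2 / 3)
    assert fam.fractions[1]["ERVL"] == pytest.approx(1 / 3)


def test_min_overlap_threshold_excludes_grazing_elements():
    peaks = [peak_at(1_000)]  # interval [950, 1050)
    reps = [repeat("chr1", 1_045, 1_200, "LTR", "ERV1")]  # 5 bp overlap
    assert repeat_composition({1: peaks}, reps).fractions[1]["LTR"] == 1.0
    assert repeat_composition({1: peaks}, reps,
                              min_overlap_bp=10).fractions[1]["LTR"] == 0.0


def test_duplicate_repeat_records_do_not_change_fractions(tmp_path):
    from tadreg.intervals import read_intervals, write_intervals
    reps = [repeat("chr1", 900, 1_100, "LTR", "ERV1", "a")]
    path = tmp_path / "reps.tsv"
    write_intervals(reps + reps, path, "repeat_tsv")  # duplicated on disk
    loaded = read_intervals(path, "repeat_tsv")
    assert len(loaded) == 1  # deduplicated at load


# --- consensus_scan --------------------------------------------------------

def oracle_regex_scan(seq, motif):
    pattern = "".join(c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]"
                      for c in motif)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    return bool(re.search(pattern, seq)) or bool(re.search(pattern, rc))


def test_motif_n_matches_everything():
    seqs = DictSequences({"chr1": "ACGT" * 1000})
    res = consensus_scan([peak_at(200)], seqs, "N")
    assert res.fraction == 1.0


def test_iupac_expansion_hand_case():
    window = "A" * 40 + "CGCCCTCTAGTG" + "A" * 49
    seqs = DictSequences({"chr1": "A" * 150 + window + "A" * 150})
    res = consensus_scan([peak_at(200)], seqs, "CGCCCYCTNSTG")
    assert res.n_with_hit == 1
    assert any(strand == "+" for _, _, strand in res.hits)


def test_all_a_sequence_never_matches():
    seqs = DictSequences({"chr1": "A" * 1000})
    res = consensus_scan([peak_at(300), peak_at(600)], seqs, "CGCCCYCTNSTG")
    assert res.fraction == 0.0


def test_non_iupac_character_errors():
    with pytest.raises(ValueError):
        iupac_regex("ACGX")


def test_reverse_complement_motif():
    assert reverse_complement_motif("CGCCCYCTNSTG") == "CASNAGRGGGCG"


def test_scan_matches_regex_oracle_on_random_sequences():
    rng = np.random.default_rng(17)
    motif = "CGCCCYCTNSTG"
    hits = 0
    for i in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=101))
        if rng.random() < 0.3:  # plant a concrete instance sometimes
            inst = "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))]
                           for c in motif)
            pos = int(rng.integers(0, 101 - len(inst)))
            seq = seq[:pos] + inst + seq[pos + len(inst):]
        seqs = DictSequences({"chr1": "X" * 0 + seq})
        got = consensus_scan([Peak("chr1", 0, 101, summit=50)], seqs, motif)
        want = oracle_regex_scan(seq, motif)
        assert (got.n_with_hit == 1) == want
        hits += got.n_with_hit
    assert hits > 0  # the oracle comparison actually exercised matches


def test_background_regions_seeded_and_bounded():
    a = random_background_regions({"chr1": 10_000, "chr2": 5_000}, 101, 50, 3)
    b = random_background_regions({"chr1": 10_000, "chr2": 5_000}, 101, 50, 3)
    assert [(r.chrom, r.start) for r in a] == [(r.chrom, r.start) for r in b]
    assert all(r.end <= 10_000 if r.chrom == "chr1" else r.end <= 5_000
               for r in a)
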