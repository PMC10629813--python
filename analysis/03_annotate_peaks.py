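#!/usr/bin/env python
"""Annotate peak clusters: genomic categories, retrotransposon composition,
and consensus motif frequency vs a random background.

Summits are classified into promoter / TTS / exonic / intronic / distal
intergenic; each cluster's repeat-class profile is compared with the others
(the planted conditioning puts LTR/ERV1 with cluster 1, SINE with cluster
2, LTR/ERVL with cluster 3); and the IUPAC consensus planted in the genome
is counted in summit-centred 101 bp windows.
"""

from pathlib import Path

import pandas as pd

from tadreg import genomic_distribution, genome_baseline, read_intervals, \
    repeat_composition
from tadreg.annotation import (FastaProvider, consensus_scan,
                               random_background_regions)

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"
SEED = 1
MOTIF = "CGCCCYCTNSTG"


def main() -> None:
    peaks = read_intervals(BUNDLE / "peaks.narrowPeak", "narrowPeak")
    genes = read_intervals(BUNDLE / "genes.tsv", "gene_tsv")
    repeats = read_intervals(BUNDLE / "repeats.tsv", "repeat_tsv")
    clusters = pd.read_csv(RESULTS / "02_clusters.tsv",
                           sep="\t").set_index("peak_id")["cluster"]
    by_cluster = {c: [p for p in peaks if clusters[p.name] == c]
                  for c in sorted(clusters.unique())}
    tads = read_intervals(BUNDLE / "tads.bed", "tad_bed")
    chrom_sizes = {}
    for t in tads:
        chrom_sizes[t.chrom] = max(chrom_sizes.get(t.chrom, 0), t.end)

    rows = [(str(c), cat, prop)
            for c, cpeaks in by_cluster.items()
            for cat, prop in genomic_distribution(cpeaks, genes).items()]
    rows += [("genome", cat, prop)
             for cat, prop in genome_baseline(genes, chrom_sizes).items()]
    dist = pd.DataFrame(rows, columns=["cluster", "category", "proportion"])
    dist.to_csv(RESULTS / "03_genomic_distribution.tsv", sep="\t", index=False)

    comp = repeat_composition(by_cluster, repeats, level="class")
    comp_rows = [(c, lab, frac) for c, d in comp.fractions.items()
                 for lab, frac in d.items()]
    pd.DataFrame(comp_rows, columns=["cluster", "repeat_class", "fraction"]
                 ).to_csv(RESULTS / "03_repeat_composition.tsv", sep="\t",
                          index=False)
    fam = repeat_composition(by_cluster, repeats, level="family",
                             parent_class="LTR")
    print("repeat classes per cluster:")
    for c, d in comp.fractions.items():
        print(f"  cluster {c}: " + ", ".join(f"{k} {v:.0%}" for k, v in d.items()))
    print("LTR family split:", {c: {k: round(v, 2) for k, v in d.items()}
                                for c, d in fam.fractions.items()})

    provider = FastaProvider(BUNDLE / "genome.fa")
    scan = consensus_scan(peaks, provider, MOTIF, window=101)
    background = random_background_regions(chrom_sizes, width=101,
                                           n=10 * len(peaks), seed=SEED)
    bg = consensus_scan(background, provider, MOTIF, window=101)
    pd.DataFrame([{"motif": MOTIF, "n_regions": scan.n_regions,
                   "n_with_hit": scan.n_with_hit, "fraction": scan.fraction,
                   "background_fraction": bg.fraction}]).to_csv(
        RESULTS / "03_motif_frequency.tsv", sep="\t", index=False)
    print(f"motif {MOTIF}: {scan.n_with_hit} in {scan.n_regions} peaks "
          f"({scan.fraction:.1%}) vs background {bg.fraction:.2%}")


if __name__ == "__main__":
    main()
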