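#!/usr/bin/env python
"""Call differential expression and test the distance-bracket association
between peaks and the up/down gene sets.

Up/down genes (adjusted p < 0.01, fold > 1.6) are tested for enrichment
among genes whose TSS lies within nested distance brackets of a peak
centre (hypergeometric upper tail), against 10 random gene sets of equal
size as a visual control.
"""

from pathlib import Path

import pandas as pd

from tadreg import call_de, de_sets, distance_bracket_association, \
    random_gene_control, read_intervals

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"
SEED = 1
BRACKETS = [5_000, 10_000, 25_000, 50_000, 100_000]


def main() -> None:
    peaks = read_intervals(BUNDLE / "peaks.narrowPeak", "narrowPeak")
    genes = read_intervals(BUNDLE / "genes.tsv", "gene_tsv")
    de_table = call_de(pd.read_csv(BUNDLE / "de_stats.tsv", sep="\t"))
    up, down, universe_ids = de_sets(de_table)
    universe = [g for g in genes if g.gene_id in universe_ids]
    print(f"DE calls: {len(up)} up, {len(down)} down of {len(universe)}")

    frames = []
    for name, gene_set in (("up", up), ("down", down)):
        assoc = distance_bracket_association(peaks, gene_set, universe,
                                             BRACKETS)
        ctrl = random_gene_control(peaks, len(gene_set), universe, BRACKETS,
                                   n_sets=10, seed=SEED)
        a = assoc.table.copy()
        a.insert(0, "gene_set", name)
        a["control_mean"] = ctrl["mean_overlap"].to_numpy()
        frames.append(a)
        print(f"  {name}: " + "; ".join(
            f"{int(r.bracket/1000)}kb k={int(r.k)} (ctrl {cm:.1f}) "
            f"p={r.p:.2g}"
            for (_, r), cm in zip(a.iterrows(), a["control_mean"])))
    pd.concat(frames).to_csv(RESULTS / "05_distance_association.tsv",
                             sep="\t", index=False)


if __name__ == "__main__":
    main()
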