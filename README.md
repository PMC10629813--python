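# tadreg

Integrative analysis of transcription-factor ChIP-seq peak classes and
TAD-scoped gene regulation, for regulatory genomicists studying
zinc-finger repressors (ZMYM2/TRIM28/ADNP-style biology) that act on
retrotransposons and regulate coding genes regionally rather than through
one-peak-one-gene links.

The pipeline: cluster peaks by multi-track signal around their centres
(k-means, k = 3, 10 kb windows), classify summits into genomic features,
measure retrotransposon class/family composition per cluster, scan for an
IUPAC consensus against a random background, call differential expression
from a statistics table (padj < 0.01, fold > 1.6), test peak–gene
association at nested distance brackets with the hypergeometric upper
tail P(X ≥ k | N, K_d, n), and run TAD-scoped tests: up/down proportions
per peak-cluster category (Fisher exact vs peak-free TADs), a gene-label
permutation test of peak/up-gene co-localization, peak-to-boundary
distances vs uniform controls (Welch t), and an adjacent-TAD
distance-mirror control (±25%).  A RIME-style spectral-count filter
(CRAPome > 50%, ribosomal, any-zero removal; mean > 4 kept) covers the
proteomics side.  A seeded synthetic-data generator plants all of this
structure — three signal archetypes, class-conditioned repeats, regional
up-regulation in archetype-1 TADs, a planted motif — so every stage is
verifiable without any external download.

## Worked example

```sh
python analysis/01_simulate.py        # synthetic bundle -> scratch/bundle
python analysis/02_cluster_signal.py  # k-means over the signal matrix
python analysis/03_annotate_peaks.py  # features, repeats, motif
python analysis/04_rime_filter.py     # spectral-count interactor filter
python analysis/05_de_association.py  # distance-bracket enrichment
python analysis/06_tad_regulation.py  # TAD-scoped regulation tests
```

Output of `02_cluster_signal.py` (seed 1):

```
cluster sizes: {1: 197, 2: 200, 3: 203}; inertia 7127.6
adjusted Rand index vs planted archetypes: 0.985
  cluster 1: {'ZMYM2': '5.88', 'TRIM28': '5.96', 'SUMO': '5.79', 'ATAC': '0.67', 'H3K18ac': '0.67', 'ADNP': '0.84'}
  cluster 2: {'ZMYM2': '5.73', 'TRIM28': '0.86', 'SUMO': '0.85', 'ATAC': '5.50', 'H3K18ac': '5.80', 'ADNP': '5.71'}
  cluster 3: {'ZMYM2': '5.86', 'TRIM28': '0.89', 'SUMO': '0.88', 'ATAC': '0.67', 'H3K18ac': '0.68', 'ADNP': '0.85'}
```

Cluster 1 is the repressive class (TRIM28/SUMO-high, ATAC-low), cluster 2
the active class (ADNP/ATAC/H3K18ac-high), cluster 3 signal-poor — the
three planted archetypes, recovered at ARI 0.985.  `06_tad_regulation.py`
then prints:

```
category  n_tads  up  down  prop_up     fisher_p
       1      16 186    29 0.865116 3.612897e-09
       2      16  67    25 0.728261 7.707442e-03
       3      19  83    25 0.768519 6.643918e-04
 no_peak      27  44    39 0.530120          NaN
co-localization with cluster-1 TADs: observed 0.830, empirical p 0.000999
mirror control: 378 peaks, 720 candidate genes, 152 up-regulated
```

TADs containing cluster-1 peaks are strongly skewed toward up-regulated
genes relative to peak-free TADs (the planted regional effect), up-genes
co-localize with cluster-1 TADs far more than label-permutation chance,
and the mirror control reports how many same-distance genes in *adjacent*
TADs are up-regulated.

The same stages run as one orchestrated command with a manifest:

```sh
tadreg simulate --seed 1 --out bundle/
tadreg run --config run.yaml
```

## Layout

- `src/tadreg/` — the library: `intervals` (types, I/O, overlap algebra),
  `signal` (matrices, k-means, profiles), `annotation` (features,
  repeats, motifs), `de` (DE calls, set overlaps, distance brackets),
  `tads` (regional tests), `rime` (spectral-count filter), `simulate`
  (generator), `pipeline` + `cli` (orchestration).
- `analysis/` — numbered drivers reproducing the analysis narrative;
  tables land in `results/`, bulky intermediates in `scratch/`.
- `tests/` — unit, property and end-to-end acceptance tests.
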