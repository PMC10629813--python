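"""Seeded synthetic-data generator for the whole analysis.

Produces an internally consistent bundle — genome FASTA, gene table, TAD
BED, repeat annotation, peak set with three planted signal archetypes,
coverage bedGraphs for six tracks, a DE statistics table with a planted
regional up-regulation, and a spectral-count table — plus truth tables, so
every analysis stage can be verified without external data.

Planted structure mirrors the assumptions the analysis exploits:

* archetype 1 peaks carry high ZMYM2/TRIM28/SUMO signal and low ATAC/
  H3K18ac (repressive chromatin), co-placed with LTR/ERV1 repeats;
* archetype 2 peaks carry high ZMYM2/ADNP/ATAC/H3K18ac (active chromatin),
  co-placed with SINE (Alu + MIR) repeats;
* archetype 3 peaks carry ZMYM2 only, co-placed with LTR/ERVL repeats;
* a configured fraction of genes inside TADs containing archetype-1 peaks
  is shifted up in the DE table, on top of a location-independent
  background of up- and down-regulated genes;
* a configured fraction of peaks has a concrete realisation of an IUPAC
  consensus written into the genome at the summit.

All randomness flows from a single master seed through named sub-streams
(numpy SeedSequence), so the same config and seed give a byte-identical
bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .de import benjamini_hochberg
from .intervals import (GeneModel, Peak, RepeatElement, TAD,
                        write_intervals)

TRACKS = ("ZMYM2", "TRIM28", "SUMO", "ATAC", "H3K18ac", "ADNP")

# archetype -> per-track mean bump height (reads per bp at the bump apex)
DEFAULT_ARCHETYPE_MEANS: dict[int, dict[str, float]] = {
    1: {"ZMYM2": 30.0, "TRIM28": 30.0, "SUMO": 30.0,
        "ATAC": 1.0, "H3K18ac": 1.0, "ADNP": 2.0},
    2: {"ZMYM2": 30.0, "TRIM28": 2.0, "SUMO": 2.0,
        "ATAC": 30.0, "H3K18ac": 30.0, "ADNP": 30.0},
    3: {"ZMYM2": 30.0, "TRIM28": 2.0, "SUMO": 2.0,
        "ATAC": 1.0, "H3K18ac": 1.0, "ADNP": 2.0},
}

# archetype -> (repeat placement rate, [(class, family), ...] drawn uniformly)
DEFAULT_REPEAT_RATES: dict[int, tuple[float, list[tuple[str, str]]]] = {
    1: (0.8, [("LTR", "ERV1")]),
    2: (0.7, [("SINE", "Alu"), ("SINE", "MIR")]),
    3: (0.7, [("LTR", "ERVL")]),
}

_SUBSTREAMS = ("genome", "tads", "genes", "peaks", "repeats", "tracks",
               "de", "motif", "spectra")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    The default scale (2 chromosomes x 10 Mb, ~60 TADs, 1200 genes, 600
    peaks in three archetypes of 200) keeps the statistics behaving like
    the real analysis while staying desk-sized.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    tad_length_range: tuple[int, int] = (250_000, 400_000)
    n_genes: int = 1200
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    strand_prob: float = 0.5
    n_peaks: tuple[int, int, int] = (200, 200, 200)
    peak_width_range: tuple[int, int] = (250, 600)
    peak_min_separation: int = 12_000
    tad_target_fraction: float = 0.25   # TAD subset hosting each archetype
    archetype_means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARCHETYPE_MEANS.items()})
    background_lambda: float = 0.5      # per-bp background coverage
    nb_dispersion: float = 8.0          # gamma shape of bump heights
    bump_sigma: float = 700.0           # bp, Gaussian bump width
    fine_bin: int = 100                 # bp, bins inside peak windows
    coarse_bin: int = 2_000             # bp, bins outside peak windows
    repeat_rates: dict[int, tuple[float, list[tuple[str, str]]]] = field(
        default_factory=lambda: {k: (r, list(fams))
                                 for k, (r, fams) in DEFAULT_REPEAT_RATES.items()})
    n_background_repeats: int = 600
    repeat_length_range: tuple[int, int] = (300, 1_000)
    de_sigma: float = 0.4               # null log2FC spread
    de_effect: float = 2.0              # planted regional log2FC shift
    de_regional_fraction: float = 0.6   # of genes in archetype-1 TADs
    de_background_up: float = 0.075     # location-independent DE, per direction
    de_background_down: float = 0.075
    motif: str = "CGCCCYCTNSTG"
    motif_plant_rate: float = 0.15
    n_proteins: int = 60
    n_true_interactors: int = 20

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def validate(self) -> None:
        if any(n < 0 for n in self.n_peaks):
            raise ValueError("peak counts must be non-negative")
        if self.tad_length_range[0] > self.chrom_length:
            raise ValueError("TADs longer than chromosomes")
        if not (0 <= self.motif_plant_rate <= 1):
            raise ValueError("motif_plant_rate must be in [0, 1]")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


# ---------------------------------------------------------------------------
# Geometry: TADs, genes, peaks
# ---------------------------------------------------------------------------

def simulate_tads(config: SimulationConfig, rng: np.random.Generator) -> list[TAD]:
    """Tile each chromosome with contiguous TADs of uniform random length."""
    tads: list[TAD] = []
    lo, hi = config.tad_length_range
    for chrom in config.chrom_names():
        pos = 0
        while pos < config.chrom_length:
            length = int(rng.integers(lo, hi + 1))
            end = min(pos + length, config.chrom_length)
            if end - pos >= lo // 2:  # drop a tiny terminal sliver
                tads.append(TAD(chrom, pos, end, tad_id=f"{chrom}_tad{len(tads)}"))
            pos = end
    return tads


def simulate_genes(config: SimulationConfig, rng: np.random.Generator
                   ) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = config.chrom_names()
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, config.chrom_length - length))
        strand = "+" if rng.random() < config.strand_prob else "-"
        genes.append(GeneModel(chrom, start, start + length,
                               strand=strand, gene_id=f"gene_{i:05d}"))
    return genes


def simulate_peaks(
    config: SimulationConfig,
    tads: list[TAD],
    rng: np.random.Generator,
) -> tuple[list[Peak], dict[str, int]]:
    """Place archetype-labelled peaks inside archetype-specific TAD subsets.

    Each archetype is hosted by a random ``tad_target_fraction`` subset of
    TADs (subsets may overlap between archetypes) so that a usable share of
    TADs stays peak-free.  Candidate centres sit on a per-TAD grid spaced
    by ``peak_min_separation`` and are drawn without replacement, so signal
    windows never collide regardless of density.
    """
    peaks: list[Peak] = []
    archetype_of: dict[str, int] = {}
    w_lo, w_hi = config.peak_width_range
    sep = config.peak_min_separation
    margin = sep // 2
    slots: dict[int, list[tuple[str, int]]] = {}  # tad index -> free centres
    for i, t in enumerate(tads):
        centres = range(t.start + margin, t.end - margin, sep)
        slots[i] = [(t.chrom, c) for c in centres]
    for arch_idx, n in enumerate(config.n_peaks, start=1):
        if n == 0:
            continue
        n_target = max(1, round(config.tad_target_fraction * len(tads)))
        order = list(rng.permutation(len(tads)))
        target_idx = sorted(order[:n_target])
        free = [(i, j) for i in target_idx for j in range(len(slots[i]))
                if slots[i][j] is not None]
        # grow the host subset when the slot capacity falls short (small
        # configs); the fraction is a floor, not a ceiling
        extra = n_target
        while len(free) < n and extra < len(tads):
            i = order[extra]
            extra += 1
            free += [(i, j) for j in range(len(slots[i]))
                     if slots[i][j] is not None]
        if len(free) < n:
            raise RuntimeError("cannot place peaks at the configured density")
        pick = rng.choice(len(free), size=n, replace=False)
        jitter = max(0, (sep - 10_000) // 2)  # keep 10 kb windows disjoint
        for sel in sorted(pick):
            i, j = free[sel]
            chrom, centre = slots[i][j]
            slots[i][j] = None
            if jitter:
                centre += int(rng.integers(-jitter, jitter + 1))
            width = int(rng.integers(w_lo, w_hi + 1))
            start = centre - width // 2
            pid = f"peak_{len(peaks):04d}"
            summit = centre + int(rng.integers(-width // 4, width // 4 + 1))
            summit = min(max(summit, start), start + width - 1)
            peaks.append(Peak(chrom, start, start + width,
                              summit=summit, score=0.0, name=pid))
            archetype_of[pid] = arch_idx
    return peaks, archetype_of


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

def simulate_repeats(
    config: SimulationConfig,
    peaks: list[Peak],
    archetype_of: dict[str, int],
    rng: np.random.Generator,
) -> list[RepeatElement]:
    """Class-labelled repeats co-placed with archetype peaks plus a uniform
    background of all classes."""
    repeats: list[RepeatElement] = []
    lo, hi = config.repeat_length_range

    def add(chrom: str, start: int, cls: str, fam: str) -> None:
        length = int(rng.integers(lo, hi + 1))
        start = max(0, min(start, config.chrom_length - length))
        name = f"{fam}_{len(repeats)}"
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(RepeatElement(chrom, start, start + length,
                                     strand=strand, repeat_name=name,
                                     repeat_class=cls, repeat_family=fam))

    for p in peaks:
        rate, choices = config.repeat_rates[archetype_of[p.name]]
        if rng.random() < rate:
            cls, fam = choices[int(rng.integers(0, len(choices)))]
            # overlap the peak interval: start within the peak span
            add(p.chrom, int(rng.integers(p.start, p.end)), cls, fam)

    background_pool = [("LTR", "ERV1"), ("LTR", "ERVL"), ("SINE", "Alu"),
                       ("SINE", "MIR"), ("LINE", "L1"), ("LINE", "L2")]
    chroms = config.chrom_names()
    for _ in range(config.n_background_repeats):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        cls, fam = background_pool[int(rng.integers(0, len(background_pool)))]
        add(chrom, int(rng.integers(0, config.chrom_length)), cls, fam)
    return repeats


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def simulate_signal_tracks(
    config: SimulationConfig,
    peaks: list[Peak],
    archetype_of: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-track bedGraph frames with Gaussian bumps at peaks.

    Bump apex heights are gamma-distributed around the archetype mean
    (shape = ``nb_dispersion``, a gamma-Poisson / negative-binomial noise
    model); bin values are Poisson reads over the bin divided by bin width.
    Fine bins cover peak windows, coarse bins the background.
    """
    window = 10_000
    half = window // 2
    frames: dict[str, list[pd.DataFrame]] = {t: [] for t in TRACKS}
    by_chrom: dict[str, list[Peak]] = {c: [] for c in config.chrom_names()}
    for p in peaks:
        by_chrom[p.chrom].append(p)

    heights = {
        t: {p.name: rng.gamma(config.nb_dispersion,
                              config.archetype_means[archetype_of[p.name]][t]
                              / config.nb_dispersion)
            for p in peaks}
        for t in TRACKS
    }

    for chrom in config.chrom_names():
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: p.centre)
        windows = [(max(0, p.centre - half),
                    min(config.chrom_length, p.centre + half), p)
                   for p in chrom_peaks]
        # breakpoints of fine (peak) and coarse (gap) regions
        for track in TRACKS:
            starts: list[np.ndarray] = []
            ends: list[np.ndarray] = []
            values: list[np.ndarray] = []
            cursor = 0
            lam = config.background_lambda
            for lo, hi, p in windows + [(config.chrom_length,
                                         config.chrom_length, None)]:
                if lo > cursor:  # coarse background bins over the gap
                    edges = np.arange(cursor, lo, config.coarse_bin)
                    edges = np.append(edges, lo)
                    widths = np.diff(edges)
                    reads = rng.poisson(lam * widths)
                    starts.append(edges[:-1])
                    ends.append(edges[1:])
                    values.append(reads / widths)
                if p is None:
                    break
                edges = np.arange(lo, hi, config.fine_bin)
                edges = np.append(edges, hi)
                mids = (edges[:-1] + edges[1:]) / 2
                widths = np.diff(edges)
                h = heights[track][p.name]
                mu = lam + h * np.exp(-((mids - p.centre) ** 2)
                                      / (2 * config.bump_sigma ** 2))
                reads = rng.poisson(mu * widths)
                starts.append(edges[:-1])
                ends.append(edges[1:])
                values.append(reads / widths)
                cursor = hi
            frames[track].append(pd.DataFrame({
                "chrom": chrom,
                "start": np.concatenate(starts).astype(np.int64),
                "end": np.concatenate(ends).astype(np.int64),
                "value": np.round(np.concatenate(values), 6),
            }))
    return {t: pd.concat(fs, ignore_index=True) for t, fs in frames.items()}


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def simulate_de_table(
    config: SimulationConfig,
    genes: list[GeneModel],
    arch1_tad_ids: set[str],
    gene_tad: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """DE statistics with planted regional and background effects.

    Null genes: log2FC ~ N(0, sigma).  Background DE genes (random subsets
    of all genes, both directions) are shifted by +/-``de_effect``.
    Regional genes — a fraction of the genes whose TAD contains an
    archetype-1 peak — are shifted by +``de_effect``.  p-values come from
    the z-score of the shift-free model and are BH-adjusted, so thresholds
    behave coherently; the ``truth`` column records the planted label.
    """
    n = len(genes)
    ids = [g.gene_id for g in genes]
    shift = np.zeros(n)
    truth = np.array(["null"] * n, dtype=object)

    order = rng.permutation(n)
    n_up = round(config.de_background_up * n)
    n_down = round(config.de_background_down * n)
    bg_up, bg_down = order[:n_up], order[n_up:n_up + n_down]
    shift[bg_up] += config.de_effect
    shift[bg_down] -= config.de_effect
    truth[bg_up] = "up"
    truth[bg_down] = "down"

    regional_pool = [i for i, g in enumerate(genes)
                     if gene_tad.get(g.gene_id) in arch1_tad_ids
                     and truth[i] == "null"]
    n_reg = round(config.de_regional_fraction * len(regional_pool))
    if n_reg and config.de_effect != 0:
        chosen = rng.choice(len(regional_pool), size=n_reg, replace=False)
        for j in chosen:
            i = regional_pool[j]
            shift[i] += config.de_effect
            truth[i] = "up"
    elif n_reg:
        # effect size zero: regional genes stay null
        pass

    lfc = rng.normal(shift, config.de_sigma)
    z = lfc / config.de_sigma
    from scipy import stats as sstats
    p = 2 * sstats.norm.sf(np.abs(z))
    padj = benjamini_hochberg(p)
    return pd.DataFrame({
        "gene_id": ids,
        "log2_fold_change": np.round(lfc, 6),
        "p_value": p,
        "adjusted_p": padj,
        "truth": truth,
    })


# ---------------------------------------------------------------------------
# Genome FASTA + motif planting
# ---------------------------------------------------------------------------

def _concrete_motif(motif: str, rng: np.random.Generator) -> str:
    from .annotation import IUPAC
    return "".join(IUPAC[ch][int(rng.integers(0, len(IUPAC[ch])))]
                   for ch in motif.upper())


def simulate_genome(
    config: SimulationConfig,
    peaks: list[Peak],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Random ACGT genome with the consensus motif written at a configured
    fraction of peak summits.  Returns per-chromosome byte arrays and the
    planted-motif truth table."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {c: bases[rng.integers(0, 4, size=config.chrom_length)].copy()
              for c in config.chrom_names()}
    planted = []
    for p in peaks:
        if rng.random() < config.motif_plant_rate:
            concrete = _concrete_motif(config.motif, rng)
            pos = p.anchor - len(concrete) // 2
            pos = max(0, min(pos, config.chrom_length - len(concrete)))
            genome[p.chrom][pos:pos + len(concrete)] = \
                np.frombuffer(concrete.encode(), dtype="S1")
            planted.append((p.name, p.chrom, pos, concrete))
    truth = pd.DataFrame(planted, columns=["peak_id", "chrom", "pos", "sequence"])
    return genome, truth


def write_fasta(genome: dict[str, np.ndarray], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            seq = arr.tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Spectral counts
# ---------------------------------------------------------------------------

def simulate_spectral_counts(config: SimulationConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Toy RIME table: true interactors with solid counts and low CRAPome
    frequency, plus contaminants, ribosomal proteins and dropouts."""
    rows = []
    n_true = config.n_true_interactors
    for i in range(config.n_proteins):
        pid = f"PROT{i:03d}"
        if i < n_true:  # true interactors
            counts = rng.poisson(12, size=3) + 1
            crapome = rng.uniform(0, 0.3)
            ribo = False
            truth = "interactor"
        elif i < n_true + (config.n_proteins - n_true) // 3:
            counts = rng.poisson(20, size=3) + 1       # frequent contaminant
            crapome = rng.uniform(0.6, 1.0)
            ribo = False
            truth = "contaminant"
        elif i < n_true + 2 * (config.n_proteins - n_true) // 3:
            counts = rng.poisson(8, size=3) + 1        # ribosomal
            crapome = rng.uniform(0, 0.5)
            ribo = True
            truth = "ribosomal"
        else:                                          # dropout / low count
            counts = rng.poisson(3, size=3)
            counts[int(rng.integers(0, 3))] = 0
            crapome = rng.uniform(0, 0.4)
            ribo = False
            truth = "dropout"
        rows.append((pid, *counts.tolist(), round(float(crapome), 4), ribo, truth))
    return pd.DataFrame(rows, columns=["protein_id", "exp1", "exp2", "exp3",
                                       "crapome_frequency", "is_ribosomal",
                                       "truth"])


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """In-memory handles plus on-disk paths of a simulated dataset."""

    out_dir: Path
    config: SimulationConfig
    tads: list[TAD]
    genes: list[GeneModel]
    peaks: list[Peak]
    archetype_of: dict[str, int]
    repeats: list[RepeatElement]
    de_table: pd.DataFrame
    spectral: pd.DataFrame
    motif_truth: pd.DataFrame

    @property
    def paths(self) -> dict[str, Path]:
        d = self.out_dir
        p = {
            "genome": d / "genome.fa",
            "genes": d / "genes.tsv",
            "tads": d / "tads.bed",
            "repeats": d / "repeats.tsv",
            "peaks": d / "peaks.narrowPeak",
            "de": d / "de_stats.tsv",
            "spectral": d / "spectral_counts.tsv",
            "tracks_yaml": d / "tracks.yaml",
            "truth_archetypes": d / "truth" / "peak_archetypes.tsv",
            "truth_de": d / "truth" / "de_truth.tsv",
            "truth_motif": d / "truth" / "motif_positions.tsv",
        }
        for t in TRACKS:
            p[f"track_{t}"] = d / "tracks" / f"{t}.bedGraph"
        return p


def simulate_regional_dataset(config: SimulationConfig) -> dict:
    """Geometry + DE only (no genome/tracks/repeats): the light bundle used
    for replicated regional-effect and calibration studies."""
    config.validate()
    rngs = _streams(config.seed)
    tads = simulate_tads(config, rngs["tads"])
    genes = simulate_genes(config, rngs["genes"])
    peaks, archetype_of = simulate_peaks(config, tads, rngs["peaks"])
    from .tads import assign_to_tads
    assignment = assign_to_tads(peaks, genes, tads)
    arch1 = {assignment.peak_tad[pid] for pid, a in archetype_of.items()
             if a == 1 and pid in assignment.peak_tad}
    de = simulate_de_table(config, genes, arch1, assignment.gene_tad,
                           rngs["de"])
    return {"tads": tads, "genes": genes, "peaks": peaks,
            "archetype_of": archetype_of, "assignment": assignment,
            "arch1_tads": arch1, "de_table": de}


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> Bundle:
    """Generate and write the full bundle; same config + seed gives
    byte-identical files."""
    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "tracks").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    rngs = _streams(config.seed)

    tads = simulate_tads(config, rngs["tads"])
    genes = simulate_genes(config, rngs["genes"])
    peaks, archetype_of = simulate_peaks(config, tads, rngs["peaks"])
    repeats = simulate_repeats(config, peaks, archetype_of, rngs["repeats"])
    repeats = sorted(repeats, key=lambda r: (r.chrom, r.start))
    tracks = simulate_signal_tracks(config, peaks, archetype_of, rngs["tracks"])
    from .tads import assign_to_tads
    assignment = assign_to_tads(peaks, genes, tads)
    arch1 = {assignment.peak_tad[pid] for pid, a in archetype_of.items()
             if a == 1 and pid in assignment.peak_tad}
    de = simulate_de_table(config, genes, arch1, assignment.gene_tad, rngs["de"])
    genome, motif_truth = simulate_genome(config, peaks, rngs["motif"])
    spectral = simulate_spectral_counts(config, rngs["spectra"])

    bundle = Bundle(out_dir=out_dir, config=config, tads=tads, genes=genes,
                    peaks=peaks, archetype_of=archetype_of, repeats=repeats,
                    de_table=de, spectral=spectral, motif_truth=motif_truth)
    paths = bundle.paths

    write_fasta(genome, paths["genome"])
    write_intervals(genes, paths["genes"], "gene_tsv")
    write_intervals(tads, paths["tads"], "tad_bed")
    write_intervals(repeats, paths["repeats"], "repeat_tsv")
    write_intervals(peaks, paths["peaks"], "narrowPeak")
    de.drop(columns=["truth"]).to_csv(paths["de"], sep="\t", index=False)
    spectral.drop(columns=["truth"]).to_csv(paths["spectral"], sep="\t",
                                            index=False)
    for t, frame in tracks.items():
        frame.to_csv(paths[f"track_{t}"], sep="\t", index=False, header=False)
    with open(paths["tracks_yaml"], "w") as fh:
        fh.write("tracks:\n")
        for t in TRACKS:
            fh.write(f"  {t}: tracks/{t}.bedGraph\n")

    pd.DataFrame(sorted(archetype_of.items()),
                 columns=["peak_id", "archetype"]).to_csv(
        paths["truth_archetypes"], sep="\t", index=False)
    de[["gene_id", "truth"]].to_csv(paths["truth_de"], sep="\t", index=False)
    motif_truth.to_csv(paths["truth_motif"], sep="\t", index=False)
    return bundle
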