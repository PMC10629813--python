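"""End-to-end orchestration: cluster -> annotate -> repeats/motif -> RIME ->
DE association -> TAD analyses, with a JSON run manifest.

Each stage writes its own TSVs into the output directory and never mutates
another stage's outputs; the manifest records package version, seed, every
parameter value, and input checksums so a run is reproducible from it
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (FastaProvider, consensus_scan, genomic_distribution,
                         genome_baseline, random_background_regions,
                         repeat_composition)
from .de import (call_de, de_sets, distance_bracket_association,
                 random_gene_control)
from .intervals import read_intervals
from .rime import filter_interactors, load_spectral_counts
from .signal import (CoverageTrack, cluster_peaks, cluster_profiles,
                     compute_signal_matrix, profiles_to_frame)
from .tads import (adjacent_tad_mirror, assign_to_tads,
                   boundary_distance_test, colocalization_permutation_test,
                   tad_direction_proportions)

logger = logging.getLogger(__name__)

STAGES = ("cluster", "annotate", "repeats", "rime", "associate", "tad")


@dataclass
class RunConfig:
    """Inputs and stage parameters; defaults follow the analysis' printed
    values (10 kb window, k = 3, fold 1.6, alpha 0.01, +/-25% tolerance,
    10 control gene sets, 2 control region sets)."""

    peaks: str = ""
    tracks: str = ""            # YAML mapping label -> bedGraph path
    genes: str = ""
    tads: str = ""
    repeats: str = ""
    de: str = ""
    spectral_counts: str = ""
    genome: str = ""            # FASTA; motif stage skipped when empty
    out_dir: str = "tadreg_out"

    window: int = 10_000
    n_bins: int = 100
    k: int = 3
    seed: int = 0
    n_init: int = 25
    repressive_track: str | None = "TRIM28"
    fold_change: float = 1.6
    alpha: float = 0.01
    brackets: tuple[int, ...] = (5_000, 10_000, 25_000, 50_000, 100_000)
    n_control_gene_sets: int = 10
    motif: str = "CGCCCYCTNSTG"
    motif_window: int = 101
    motif_background_factor: int = 10
    n_perm: int = 1000
    tolerance: float = 0.25
    n_control_regions: int = 2360
    n_control_region_sets: int = 2
    crapome_max: float = 0.5
    min_avg_count: float = 4.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "brackets" in data:
            data["brackets"] = tuple(int(b) for b in data["brackets"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_tracks(tracks_yaml: Path) -> list[CoverageTrack]:
    spec = yaml.safe_load(tracks_yaml.read_text())
    base = tracks_yaml.parent
    return [CoverageTrack.from_bedgraph(base / rel, label)
            for label, rel in spec["tracks"].items()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    Inputs are validated up front (dry run) so a missing file aborts before
    any stage writes output.
    """
    inputs = {k: Path(getattr(config, k))
              for k in ("peaks", "tracks", "genes", "tads", "repeats", "de",
                        "spectral_counts")
              if getattr(config, k)}
    if config.genome:
        inputs["genome"] = Path(config.genome)
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {', '.join(missing)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "tadreg",
        "version": __version__,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "input_checksums": {k: _sha256(p) for k, p in inputs.items()},
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %-9s %s", stage,
                    " ".join(f"{k}={v}" for k, v in info.items()))

    try:
        peaks = read_intervals(config.peaks, "narrowPeak")
        genes = read_intervals(config.genes, "gene_tsv")
        tads = read_intervals(config.tads, "tad_bed")
        repeats = read_intervals(config.repeats, "repeat_tsv")
        de_stats = pd.read_csv(config.de, sep="\t")

        # --- cluster ---------------------------------------------------
        tracks = _load_tracks(Path(config.tracks))
        matrix = compute_signal_matrix(peaks, tracks, window=config.window,
                                       n_bins=config.n_bins)
        assignment = cluster_peaks(matrix, k=config.k, seed=config.seed,
                                   n_init=config.n_init,
                                   repressive_track=config.repressive_track)
        profiles, sizes = cluster_profiles(matrix, assignment)
        pd.DataFrame(sorted(assignment.labels.items()),
                     columns=["peak_id", "cluster"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        profiles_to_frame(profiles, sizes).to_csv(
            out / "cluster_profiles.tsv", sep="\t", index=False)
        record("cluster", n_peaks=len(peaks), k=config.k,
               inertia=round(assignment.inertia, 3),
               sizes={str(c): n for c, n in sizes.items()})

        peaks_by_cluster = {
            c: [p for p in peaks if assignment.labels[p.name] == c]
            for c in range(1, config.k + 1)
        }

        # --- annotate --------------------------------------------------
        chrom_sizes: dict[str, int] = {}
        for t in tads:
            chrom_sizes[t.chrom] = max(chrom_sizes.get(t.chrom, 0), t.end)
        rows = []
        for c, cpeaks in peaks_by_cluster.items():
            if not cpeaks:
                continue
            dist = genomic_distribution(cpeaks, genes)
            for cat, prop in dist.items():
                rows.append((str(c), cat, prop))
        for cat, prop in genome_baseline(genes, chrom_sizes).items():
            rows.append(("genome", cat, prop))
        pd.DataFrame(rows, columns=["cluster", "category", "proportion"]).to_csv(
            out / "genomic_distribution.tsv", sep="\t", index=False)
        record("annotate", n_genes=len(genes), categories=5)

        # --- repeats (+ motif when a genome is given) -------------------
        comp = repeat_composition(peaks_by_cluster, repeats, level="class")
        rows = [(str(c), lab, frac) for c, d in comp.fractions.items()
                for lab, frac in d.items()]
        pd.DataFrame(rows, columns=["cluster", "repeat_class", "fraction"]).to_csv(
            out / "repeat_composition.tsv", sep="\t", index=False)
        motif_summary = {}
        if config.genome:
            provider = FastaProvider(config.genome)
            scan = consensus_scan(peaks, provider, config.motif,
                                  window=config.motif_window)
            background = random_background_regions(
                chrom_sizes, width=config.motif_window,
                n=config.motif_background_factor * len(peaks),
                seed=config.seed)
            bg_scan = consensus_scan(background, provider, config.motif,
                                     window=config.motif_window)
            motif_summary = {"fraction": scan.fraction,
                             "background_fraction": bg_scan.fraction}
            pd.DataFrame([{"motif": config.motif, "n_regions": scan.n_regions,
                           "n_with_hit": scan.n_with_hit,
                           "fraction": scan.fraction,
                           "background_fraction": bg_scan.fraction}]).to_csv(
                out / "motif_frequency.tsv", sep="\t", index=False)
        record("repeats", n_repeats=len(repeats), **motif_summary)

        # --- rime -------------------------------------------------------
        spectra = load_spectral_counts(config.spectral_counts)
        interactors = filter_interactors(spectra, crapome_max=config.crapome_max,
                                         min_avg=config.min_avg_count)
        interactors.to_csv(out / "interactors.tsv", sep="\t")
        record("rime", n_input=len(spectra), n_kept=len(interactors))

        # --- associate ---------------------------------------------------
        de_table = call_de(de_stats, fold_change=config.fold_change,
                           alpha=config.alpha)
        up, down, universe_ids = de_sets(de_table)
        universe = [g for g in genes if g.gene_id in universe_ids]
        assoc_rows = []
        for set_name, gene_set in (("up", up), ("down", down)):
            assoc = distance_bracket_association(
                peaks, gene_set, universe, list(config.brackets))
            a = assoc.table.copy()
            a.insert(0, "gene_set", set_name)
            assoc_rows.append(a)
            ctrl = random_gene_control(peaks, len(gene_set), universe,
                                       list(config.brackets),
                                       n_sets=config.n_control_gene_sets,
                                       seed=config.seed)
            ctrl.insert(0, "gene_set", set_name)
            ctrl.to_csv(out / f"random_gene_control_{set_name}.tsv",
                        sep="\t", index=False)
        pd.concat(assoc_rows).to_csv(out / "distance_association.tsv",
                                     sep="\t", index=False)
        record("associate", n_up=len(up), n_down=len(down),
               universe=len(universe))

        # --- tad ---------------------------------------------------------
        tad_assignment = assign_to_tads(peaks, genes, tads)
        direction = tad_direction_proportions(tad_assignment,
                                              assignment.labels, up, down)
        direction.to_csv(out / "tad_direction.tsv", sep="\t", index=False)
        obs, perm_p = colocalization_permutation_test(
            up, peaks_by_cluster.get(1, []), tad_assignment,
            n_perm=config.n_perm, seed=config.seed)
        _, _, boundary = boundary_distance_test(
            peaks_by_cluster, tads, n_control=config.n_control_regions,
            n_control_sets=config.n_control_region_sets, seed=config.seed)
        boundary.to_csv(out / "boundary_distance.tsv", sep="\t", index=False)
        mirror = adjacent_tad_mirror(peaks, up, genes, tads, tad_assignment,
                                     tolerance=config.tolerance)
        pd.DataFrame([{
            "colocalization_observed": obs,
            "colocalization_p": perm_p,
            "mirror_n_peaks": mirror.n_qualifying_peaks,
            "mirror_n_genes": mirror.n_candidate_genes,
            "mirror_n_up": mirror.n_up_candidates,
        }]).to_csv(out / "tad_summary.tsv", sep="\t", index=False)
        record("tad", n_tads=len(tads), colocalization_p=perm_p,
               mirror=(mirror.n_qualifying_peaks, mirror.n_candidate_genes,
                       mirror.n_up_candidates))
    except Exception as exc:
        done = len(manifest["stages"])
        failing = STAGES[done] if done < len(STAGES) else "report"
        raise RuntimeError(f"pipeline failed at stage {failing!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    summary = [f"tadreg {__version__} run complete; stages: "
               + ", ".join(manifest["stages"])]
    for stage, info in manifest["stages"].items():
        summary.append(f"  {stage}: " + ", ".join(f"{k}={v}"
                                                  for k, v in info.items()))
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
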