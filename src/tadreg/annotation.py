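"""Summit-based genomic-feature classification, repeat-class composition
per peak cluster, and IUPAC consensus motif scanning.

The genome is divided into five mutually exclusive categories per summit —
promoter, TTS, exonic, intronic, distal intergenic — using strand-aware
windows (promoter: 1 kb upstream to 0.1 kb downstream of the TSS; TTS:
0.1 kb upstream to 1 kb downstream of the TTS) with the precedence
promoter > tts > exonic > intronic across all genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneModel, Peak, RepeatElement, REPEAT_CLASSES

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "tts", "exonic", "intronic", "distal_intergenic")

PROMOTER_UP = 1000     # bp upstream of TSS
PROMOTER_DOWN = 100    # bp downstream of TSS
TTS_UP = 100           # bp upstream of TTS
TTS_DOWN = 1000        # bp downstream of TTS


def _gene_windows(gene: GeneModel) -> dict[str, tuple[int, int] | None]:
    """Closed [lo, hi] windows for promoter / tts / gene interior."""
    tss, tts = gene.tss, gene.tts
    if gene.strand == "+":
        promoter = (tss - PROMOTER_UP, tss + PROMOTER_DOWN)
        tts_win = (tts - TTS_UP, tts + TTS_DOWN)
        interior = (tss + PROMOTER_DOWN + 1, tts - TTS_UP - 1)
    else:
        promoter = (tss - PROMOTER_DOWN, tss + PROMOTER_UP)
        tts_win = (tts - TTS_DOWN, tts + TTS_UP)
        interior = (tts + TTS_UP + 1, tss - PROMOTER_DOWN - 1)
    if interior[0] > interior[1]:
        interior = None  # gene too short for an interior
    return {"promoter": promoter, "tts": tts_win, "interior": interior}


def classify_summit(peak: Peak, genes: Sequence[GeneModel]) -> str:
    """Assign a peak's summit (centre when no summit, logged) to one of the
    five genomic categories under promoter > tts > exonic > intronic
    precedence across all genes."""
    if peak.summit is None:
        logger.debug("peak at %s:%d has no summit; using centre",
                     peak.chrom, peak.centre)
    pos = peak.anchor
    hit = {"promoter": False, "tts": False, "exonic": False, "intronic": False}
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        win = _gene_windows(gene)
        lo, hi = win["promoter"]
        if lo <= pos <= hi:
            hit["promoter"] = True
            continue
        lo, hi = win["tts"]
        if lo <= pos <= hi:
            hit["tts"] = True
            continue
        if win["interior"] is not None:
            lo, hi = win["interior"]
            if lo <= pos <= hi:
                exons = gene.exons or (gene,)  # exon-less genes: single exon
                if any(e.start <= pos < e.end for e in exons):
                    hit["exonic"] = True
                else:
                    hit["intronic"] = True
    for cat in ("promoter", "tts", "exonic", "intronic"):
        if hit[cat]:
            return cat
    return "distal_intergenic"


def genomic_distribution(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
) -> dict[str, float]:
    """Proportion of peak summits per category (sums to 1)."""
    if not peaks:
        raise ValueError("empty peak list")
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        counts[classify_summit(p, genes)] += 1
    n = len(peaks)
    return {c: counts[c] / n for c in CATEGORIES}


def genome_baseline(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
) -> dict[str, float]:
    """Genome-wide fraction of bp per category, same windows and precedence.

    Computed by classifying every base via interval arithmetic: category
    masks are built per chromosome and higher-precedence categories mask
    lower ones.
    """
    totals = {c: 0 for c in CATEGORIES}
    for chrom, size in chrom_sizes.items():
        layers: dict[str, list[tuple[int, int]]] = {
            "promoter": [], "tts": [], "exonic": [], "intronic": []}
        for gene in genes:
            if gene.chrom != chrom:
                continue
            win = _gene_windows(gene)
            for key in ("promoter", "tts"):
                lo, hi = win[key]
                layers[key].append((max(0, lo), min(size, hi + 1)))
            if win["interior"] is not None:
                lo, hi = win["interior"]
                lo, hi = max(0, lo), min(size, hi + 1)
                exons = gene.exons or (gene,)
                for e in exons:
                    s, t = max(lo, e.start), min(hi, e.end)
                    if s < t:
                        layers["exonic"].append((s, t))
                layers["intronic"].append((lo, hi))
        covered: list[tuple[int, int]] = []
        for cat in ("promoter", "tts", "exonic", "intronic"):
            merged = _merge(layers[cat])
            new_bp = _subtract_bp(merged, covered)
            totals[cat] += new_bp
            covered = _merge(covered + merged)
        totals["distal_intergenic"] += size - sum(e - s for s, e in covered)
    genome = sum(chrom_sizes.values())
    return {c: totals[c] / genome for c in CATEGORIES}


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_bp(ivs: list[tuple[int, int]], mask: list[tuple[int, int]]) -> int:
    """bp in merged ``ivs`` not covered by merged ``mask``."""
    total = sum(e - s for s, e in ivs)
    overlap = 0
    for s, e in ivs:
        for ms, me in mask:
            overlap += max(0, min(e, me) - max(s, ms))
    return total - overlap


# ---------------------------------------------------------------------------
# Repeat composition
# ---------------------------------------------------------------------------

@dataclass
class RepeatComposition:
    level: str  # "class" or "family"
    fractions: dict[object, dict[str, float]]  # cluster -> label -> fraction
    background: dict[str, float] | None = None


def _peaks_containing(peaks: Sequence[Peak], repeats: Sequence[RepeatElement],
                      labels: Sequence[str], label_of, min_overlap_bp: int) -> dict[str, float]:
    """Fraction of peaks overlapping >= min_overlap_bp with >= 1 element of
    each label."""
    by_chrom: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda r: r.start)
    counts = {lab: 0 for lab in labels}
    for p in peaks:
        found: set[str] = set()
        for r in by_chrom.get(p.chrom, []):
            if r.start >= p.end:
                break
            if min(p.end, r.end) - max(p.start, r.start) >= min_overlap_bp:
                found.add(label_of(r))
        for lab in found:
            if lab in counts:
                counts[lab] += 1
    n = len(peaks)
    return {lab: (counts[lab] / n if n else 0.0) for lab in labels}


def repeat_composition(
    peaks_by_cluster: Mapping[object, Sequence[Peak]],
    repeats: Sequence[RepeatElement],
    level: str = "class",
    parent_class: str | None = None,
    min_overlap_bp: int = 1,
    background_peaks: Sequence[Peak] | None = None,
) -> RepeatComposition:
    """Per-cluster retrotransposon composition.

    ``level="class"``: fraction of each cluster's peaks containing >= 1
    element of each class (a peak may count for several classes).
    ``level="family"``: restricted to ``parent_class``; fractions are among
    the peaks of the cluster containing that class, per family.
    """
    if level not in ("class", "family"):
        raise ValueError(f"level must be 'class' or 'family', got {level!r}")
    if level == "family":
        if parent_class is None:
            raise ValueError("family level requires parent_class")
        repeats = [r for r in repeats if r.repeat_class == parent_class]
        families = sorted({r.repeat_family for r in repeats})

    fractions: dict[object, dict[str, float]] = {}
    for cluster, peaks in peaks_by_cluster.items():
        if level == "class":
            fractions[cluster] = _peaks_containing(
                peaks, repeats, REPEAT_CLASSES, lambda r: r.repeat_class,
                min_overlap_bp)
        else:
            class_frac = _peaks_containing(
                peaks, repeats, [parent_class], lambda r: r.repeat_class,
                min_overlap_bp)[parent_class]
            fam = _peaks_containing(peaks, repeats, families,
                                    lambda r: r.repeat_family, min_overlap_bp)
            denom = class_frac if class_frac > 0 else 1.0
            fractions[cluster] = {f: fam[f] / denom for f in families}

    background = None
    if background_peaks is not None:
        if level == "class":
            background = _peaks_containing(
                background_peaks, repeats, REPEAT_CLASSES,
                lambda r: r.repeat_class, min_overlap_bp)
        else:
            background = _peaks_containing(
                background_peaks, repeats, families,
                lambda r: r.repeat_family, min_overlap_bp)
    return RepeatComposition(level=level, fractions=fractions, background=background)


# ---------------------------------------------------------------------------
# IUPAC consensus motif scanning
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in motif")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def reverse_complement_motif(motif: str) -> str:
    return motif.upper().translate(_COMPLEMENT)[::-1]


class FastaProvider:
    """Sequence provider backed by an indexed FASTA file."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta
        self._fa = Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        return str(self._fa[chrom][start:end]).upper()


@dataclass
class MotifScanResult:
    n_regions: int
    n_with_hit: int
    fraction: float
    hits: list[tuple[int, int, str]]  # (region index, window offset, strand)


def consensus_scan(
    regions: Sequence[Peak],
    sequences,
    motif: str,
    window: int = 101,
) -> MotifScanResult:
    """Fraction of regions whose summit-centred window matches an IUPAC
    consensus on either strand.

    ``sequences`` is any object with ``fetch(chrom, start, end) -> str``.
    """
    fwd = iupac_regex(motif)
    rev = iupac_regex(reverse_complement_motif(motif))
    half = window // 2
    hits: list[tuple[int, int, str]] = []
    with_hit = 0
    for i, region in enumerate(regions):
        pos = region.anchor
        seq = sequences.fetch(region.chrom, pos - half, pos - half + window)
        found = False
        for m in fwd.finditer(seq):
            hits.append((i, m.start(), "+"))
            found = True
        for m in rev.finditer(seq):
            hits.append((i, m.start(), "-"))
            found = True
        if found:
            with_hit += 1
    n = len(regions)
    return MotifScanResult(n_regions=n, n_with_hit=with_hit,
                           fraction=with_hit / n if n else 0.0, hits=hits)


def random_background_regions(
    chrom_sizes: Mapping[str, int],
    width: int,
    n: int,
    seed: int,
) -> list[Peak]:
    """Uniformly placed equal-width control regions on the same chromosomes,
    for motif-frequency backgrounds (seeded)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out: list[Peak] = []
    for i in range(n):
        ci = rng.choice(len(chroms), p=probs)
        size = int(sizes[ci])
        start = int(rng.integers(0, max(1, size - width)))
        out.append(Peak(chroms[ci], start, start + width,
                        summit=start + width // 2, name=f"bg_{i}"))
    return out
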