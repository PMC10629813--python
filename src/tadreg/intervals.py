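"""Core genomic data types, standard-format I/O, and interval algebra.

All coordinates are 0-based half-open (`[start, end)`, BED convention)
internally.  Gene tables may be declared 1-based via a ``#coordinate_base=1``
header line and are converted at load time.

The mutual-overlap predicate implemented here is the reciprocal rule used
throughout the analysis: two intervals count as overlapping only when the
shared span covers at least a given fraction (default 30%) of *each*
interval's length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NO_TARGET = math.nan  # sentinel distance when a chromosome has no targets


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak(GenomicInterval):
    """A called peak; ``summit`` is an absolute position (or None)."""

    summit: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def anchor(self) -> int:
        """Summit when present, otherwise the interval centre."""
        return self.summit if self.summit is not None else self.centre


@dataclass(frozen=True)
class GeneModel(GenomicInterval):
    """A strand-aware gene interval.

    TSS is ``start`` on the plus strand and ``end - 1`` on the minus strand
    (the last base of the half-open interval); TTS is the opposite end.
    """

    strand: str = "+"
    gene_id: str = ""
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(f"exon {ex} outside gene body of {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TAD(GenomicInterval):
    """A topologically associating domain; the regional containment unit."""

    tad_id: str = ""


# Repeat family -> class lookup shipped with the package.  Families outside
# the lookup are only accepted under class "other".
REPEAT_FAMILY_CLASS: dict[str, str] = {
    "ERV1": "LTR",
    "ERVL": "LTR",
    "ERVL-MaLR": "LTR",
    "ERVK": "LTR",
    "Gypsy": "LTR",
    "Alu": "SINE",
    "MIR": "SINE",
    "tRNA": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "CR1": "LINE",
    "RTE": "LINE",
}

REPEAT_CLASSES = ("LTR", "SINE", "LINE", "other")


@dataclass(frozen=True)
class RepeatElement(GenomicInterval):
    strand: str = "+"
    repeat_name: str = ""
    repeat_class: str = "other"
    repeat_family: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        known = REPEAT_FAMILY_CLASS.get(self.repeat_family)
        if known is not None and known != self.repeat_class:
            raise ValueError(
                f"repeat family {self.repeat_family!r} belongs to class {known}, "
                f"not {self.repeat_class!r}"
            )
        if known is None and self.repeat_class != "other":
            raise ValueError(
                f"family {self.repeat_family!r} not in the shipped lookup; "
                f"only class 'other' accepts unlisted families"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

FORMATS = ("bed3", "bed6", "narrowPeak", "tad_bed", "repeat_tsv", "gene_tsv")

_REPEAT_COLUMNS = ["chrom", "start", "end", "strand", "repeat_name",
                   "repeat_class", "repeat_family"]
_GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_intervals(path: str | Path, format: str) -> list:
    """Read a typed interval list from a standard tab-separated format.

    Supported formats: ``bed3``, ``bed6`` (both -> GenomicInterval/Peak),
    ``narrowPeak`` (ENCODE BED6+4 -> Peak with absolute summit, -1 offset
    meaning absent), ``tad_bed`` (BED3 -> TAD, validated non-overlapping),
    ``repeat_tsv`` and ``gene_tsv`` (headered TSVs).  Input order is
    preserved.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    lines = path.read_text().splitlines()

    if format == "repeat_tsv":
        return _read_repeat_tsv(path, lines)
    if format == "gene_tsv":
        return _read_gene_tsv(path, lines)

    out: list = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        try:
            if format == "bed3" or format == "tad_bed":
                if len(cols) < 3:
                    raise ValueError("expected >= 3 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                if format == "tad_bed":
                    out.append(TAD(chrom, start, end, tad_id=f"tad_{len(out)}"))
                else:
                    out.append(GenomicInterval(chrom, start, end))
            elif format == "bed6":
                if len(cols) < 6:
                    raise ValueError("expected >= 6 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                score = float(cols[4]) if cols[4] not in (".", "") else None
                out.append(Peak(chrom, start, end, name=cols[3], score=score))
            elif format == "narrowPeak":
                if len(cols) < 10:
                    raise ValueError("expected 10 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                offset = int(cols[9])
                summit = start + offset if offset >= 0 else None
                score = float(cols[6])
                out.append(Peak(chrom, start, end, summit=summit,
                                score=score, name=cols[3]))
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
    if format == "tad_bed":
        validate_tads(out)
    return out


def _read_repeat_tsv(path: Path, lines: list[str]) -> list[RepeatElement]:
    body = [l for l in lines if l.strip()]
    if not body:
        raise ValueError(f"{path}: repeat_tsv requires a header line")
    header = body[0].rstrip("\n").split("\t")
    if header[: len(_REPEAT_COLUMNS)] != _REPEAT_COLUMNS:
        raise ValueError(f"{path}: bad repeat_tsv header {header!r}")
    out: list[RepeatElement] = []
    seen: set[tuple] = set()
    for lineno, line in enumerate(body[1:], start=2):
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 7:
            raise _parse_error(path, lineno, "expected 7 columns")
        try:
            rec = RepeatElement(cols[0], int(cols[1]), int(cols[2]),
                                strand=cols[3], repeat_name=cols[4],
                                repeat_class=cols[5], repeat_family=cols[6])
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
        key = (rec.chrom, rec.start, rec.end, rec.repeat_name)
        if key in seen:  # deduplicate exact records
            continue
        seen.add(key)
        out.append(rec)
    return out


def _read_gene_tsv(path: Path, lines: list[str]) -> list[GeneModel]:
    base = 0
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            flag = line.lstrip("#").strip()
            if flag.startswith("coordinate_base="):
                base = int(flag.split("=", 1)[1])
                if base not in (0, 1):
                    raise _parse_error(path, lineno, f"coordinate_base must be 0 or 1")
            continue
        if line.strip():
            body.append((lineno, line))
    if not body:
        raise ValueError(f"{path}: gene_tsv requires a header line")
    header = body[0][1].rstrip("\n").split("\t")
    if header[: len(_GENE_COLUMNS)] != _GENE_COLUMNS:
        raise ValueError(f"{path}: bad gene_tsv header {header!r}")
    out: list[GeneModel] = []
    for lineno, line in body[1:]:
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise _parse_error(path, lineno, "expected 5 columns")
        try:
            start = int(cols[1]) - (1 if base == 1 else 0)
            end = int(cols[2])  # 1-based inclusive end == 0-based exclusive end
            out.append(GeneModel(cols[0], start, end, strand=cols[3],
                                 gene_id=cols[4]))
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
    return out


def write_intervals(records: Sequence, path: str | Path, format: str) -> None:
    """Write records back out in the named format (inverse of read_intervals)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    rows: list[str] = []
    if format == "repeat_tsv":
        rows.append("\t".join(_REPEAT_COLUMNS))
        for r in records:
            rows.append("\t".join([r.chrom, str(r.start), str(r.end), r.strand,
                                   r.repeat_name, r.repeat_class, r.repeat_family]))
    elif format == "gene_tsv":
        rows.append("\t".join(_GENE_COLUMNS))
        for g in records:
            rows.append("\t".join([g.chrom, str(g.start), str(g.end),
                                   g.strand, g.gene_id]))
    else:
        for i, r in enumerate(records):
            if format in ("bed3", "tad_bed"):
                rows.append(f"{r.chrom}\t{r.start}\t{r.end}")
            elif format == "bed6":
                score = "." if getattr(r, "score", None) is None else f"{r.score:g}"
                rows.append(f"{r.chrom}\t{r.start}\t{r.end}\t"
                            f"{getattr(r, 'name', None) or f'region_{i}'}\t{score}\t.")
            elif format == "narrowPeak":
                offset = -1 if r.summit is None else r.summit - r.start
                score = 0.0 if r.score is None else r.score
                rows.append(f"{r.chrom}\t{r.start}\t{r.end}\t"
                            f"{r.name or f'peak_{i}'}\t0\t.\t{score:g}\t-1\t-1\t{offset}")
    path.write_text("\n".join(rows) + ("\n" if rows else ""))


def validate_tads(tads: Sequence[TAD]) -> None:
    """Raise if any two TADs on one chromosome overlap."""
    by_chrom: dict[str, list[TAD]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts = sorted(ts, key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})"
                )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared span in bp (0 if disjoint or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def mutual_overlap(a: GenomicInterval, b: GenomicInterval, frac: float = 0.3) -> bool:
    """Reciprocal overlap rule: shared span >= ``frac`` of each length."""
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    ov = overlap_bp(a, b)
    return ov >= frac * a.length and ov >= frac * b.length


@dataclass
class OverlapSummary:
    shared_a: int
    shared_b: int
    a_only: int
    b_only: int
    pairs: list[tuple[int, int]]  # (index in A, index in B) qualifying pairs


def overlap_peak_sets(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    frac: float = 0.3,
) -> OverlapSummary:
    """Count peaks in each set with >= 1 mutual-overlap partner in the other.

    A sweep over sort-ordered intervals keeps this near-linear; the brute
    force oracle in the tests checks equivalence.
    """
    order_b: dict[str, list[tuple[int, int, int]]] = {}
    for j, b in enumerate(peaks_b):
        order_b.setdefault(b.chrom, []).append((b.start, b.end, j))
    for chrom in order_b:
        order_b[chrom].sort()

    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for i, a in enumerate(peaks_a):
        cand = order_b.get(a.chrom, [])
        if not cand:
            continue
        starts = [c[0] for c in cand]
        # only intervals starting before a.end can overlap a
        hi = np.searchsorted(starts, a.end)
        for start, end, j in cand[:hi]:
            if end <= a.start:
                continue
            if mutual_overlap(a, peaks_b[j], frac):
                pairs.append((i, j))
                hit_a.add(i)
                hit_b.add(j)
    if not (set(p.chrom for p in peaks_a) & set(p.chrom for p in peaks_b)) and \
            peaks_a and peaks_b:
        logger.warning("peak sets share zero chromosome names")
    return OverlapSummary(
        shared_a=len(hit_a),
        shared_b=len(hit_b),
        a_only=len(peaks_a) - len(hit_a),
        b_only=len(peaks_b) - len(hit_b),
        pairs=pairs,
    )


def distance_to_nearest(
    points: Iterable[tuple[str, int]],
    targets: Sequence,
) -> list[float]:
    """Distance (bp) from each (chrom, position) point to the nearest target.

    Targets may be intervals (distance 0 inside, else bp to the nearest
    edge) or (chrom, position) points.  Points on chromosomes without any
    target get ``nan`` and are excluded from summaries by callers.  Ties go
    to the first target in sorted genomic order (irrelevant to the value).
    """
    iv_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        if isinstance(t, GenomicInterval):
            grouped.setdefault(t.chrom, []).append((t.start, t.end))
        else:
            chrom, pos = t
            grouped.setdefault(chrom, []).append((pos, pos + 1))
    for chrom, ivs in grouped.items():
        ivs.sort()
        iv_by_chrom[chrom] = (
            np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64),
        )

    out: list[float] = []
    for chrom, pos in points:
        if chrom not in iv_by_chrom:
            out.append(NO_TARGET)
            continue
        starts, ends = iv_by_chrom[chrom]
        out.append(float(_nearest_scan(starts, ends, pos)))
    return out


def _nearest_scan(starts: np.ndarray, ends: np.ndarray, pos: int) -> int:
    """Exact nearest-edge distance against sorted intervals."""
    i = int(np.searchsorted(starts, pos, side="right"))
    best = None
    # left neighbours: running max of ends among starts <= pos
    if i > 0:
        left_max_end = int(ends[:i].max())
        if left_max_end > pos:
            return 0  # inside an interval
        best = pos - (left_max_end - 1)
    if i < len(starts):
        d = int(starts[i]) - pos
        if best is None or d < best:
            best = d
    return best
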