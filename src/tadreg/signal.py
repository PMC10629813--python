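"""Windowed multi-track signal matrices around peak centres and k-means
peak clustering.

Each peak contributes one row: for every coverage track the 10 kb window
centred on the peak centre is split into fixed-width bins and each bin holds
the mean per-base coverage.  Rows are clustered with k-means (k = 3 by
default) after per-track scaling, and per-cluster mean profiles ("tag
density") summarise each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import Peak

logger = logging.getLogger(__name__)


class CoverageTrack:
    """A per-chromosome step function of non-negative coverage (bedGraph)."""

    def __init__(self, label: str,
                 segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.label = label
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping bedGraph segments on {chrom}")
            if np.any(values < 0):
                raise ValueError(f"negative coverage on {chrom}")
            # prefix integral of coverage at segment ends for O(log n) queries
            integral = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            self._chrom[chrom] = (starts, ends, values, integral)

    @classmethod
    def from_bedgraph(cls, path: str | Path, label: str | None = None) -> "CoverageTrack":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        segs = {
            str(chrom): (g["start"].to_numpy(), g["end"].to_numpy(),
                         g["value"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=False)
        }
        return cls(label or path.stem, segs)

    def chromosomes(self) -> set[str]:
        return set(self._chrom)

    def _cum(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of coverage over (-inf, x) for sorted query positions."""
        starts, ends, values, integral = self._chrom[chrom]
        i = np.searchsorted(ends, x, side="right")  # segments fully left of x
        base = integral[i]
        # partial contribution of the segment containing x, if any
        inside = (i < len(starts)) & (x > starts[np.minimum(i, len(starts) - 1)])
        j = np.minimum(i, len(starts) - 1)
        partial = np.where(inside, (np.minimum(x, ends[j]) - starts[j]) * values[j], 0.0)
        return base + partial

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        """Mean per-base coverage in ``n_bins`` equal bins over [start, end).

        Positions outside the track's data (including negative coordinates)
        contribute zero coverage.
        """
        if chrom not in self._chrom:
            return np.zeros(n_bins)
        edges = np.linspace(start, end, n_bins + 1).astype(np.int64)
        cum = self._cum(chrom, np.maximum(edges, 0))
        widths = np.diff(edges)
        return np.diff(cum) / widths


@dataclass
class SignalMatrix:
    """peaks x (tracks * bins) windowed-coverage matrix."""

    peaks: list[Peak]
    peak_ids: list[str]
    track_labels: list[str]
    window: int
    n_bins: int
    values: np.ndarray  # shape (n_peaks, n_tracks * n_bins)
    normalization: str = "raw"

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n != len(self.peaks) or m != len(self.track_labels) * self.n_bins:
            raise ValueError("matrix shape inconsistent with peaks/tracks/bins")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("matrix values must be finite and non-negative")

    def track_block(self, label: str) -> np.ndarray:
        i = self.track_labels.index(label)
        return self.values[:, i * self.n_bins:(i + 1) * self.n_bins]

    def per_track_scaled(self, percentile: float = 95.0) -> "SignalMatrix":
        """Scale each track's columns by that track's global upper-percentile
        bin value so no single deep track dominates Euclidean distance."""
        scaled = self.values.copy()
        for i in range(len(self.track_labels)):
            block = scaled[:, i * self.n_bins:(i + 1) * self.n_bins]
            denom = np.percentile(block, percentile)
            if denom > 0:
                block /= denom
        return replace(self, values=scaled, normalization="per_track_scaled")

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"{t}:{b}" for t in self.track_labels for b in range(self.n_bins)]
        df = pd.DataFrame(self.values, index=self.peak_ids, columns=cols)
        df.index.name = "peak_id"
        df.to_csv(path, sep="\t")


def compute_signal_matrix(
    peaks: list[Peak],
    tracks: list[CoverageTrack],
    window: int = 10_000,
    n_bins: int = 100,
) -> SignalMatrix:
    """Windowed mean coverage per bin, per track, centred on peak centres."""
    if window % n_bins != 0:
        raise ValueError(f"window {window} not divisible by n_bins {n_bins}")
    values = np.zeros((len(peaks), len(tracks) * n_bins))
    warned: set[tuple[str, str]] = set()
    for j, track in enumerate(tracks):
        chroms = track.chromosomes()
        for i, p in enumerate(peaks):
            if p.chrom not in chroms:
                if (track.label, p.chrom) not in warned:
                    logger.warning("track %s has no data on %s; zeros used",
                                   track.label, p.chrom)
                    warned.add((track.label, p.chrom))
                continue
            lo = p.centre - window // 2
            values[i, j * n_bins:(j + 1) * n_bins] = track.binned_means(
                p.chrom, lo, lo + window, n_bins)
    peak_ids = [p.name or f"peak_{i}" for i, p in enumerate(peaks)]
    return SignalMatrix(peaks=list(peaks), peak_ids=peak_ids,
                        track_labels=[t.label for t in tracks],
                        window=window, n_bins=n_bins, values=values)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # peak_id -> cluster label in 1..k
    k: int
    seed: int
    inertia: float

    def label_array(self, peak_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[pid] for pid in peak_ids])


def cluster_peaks(
    matrix: SignalMatrix,
    k: int = 3,
    seed: int = 0,
    n_init: int = 25,
    scale: bool = True,
    repressive_track: str | None = None,
) -> ClusterAssignment:
    """k-means over matrix rows with deterministic relabelling.

    Fitted labels are arbitrary, so clusters are renumbered 1..k
    semantically: when ``repressive_track`` is given, the cluster with the
    highest mean on that track becomes cluster 1 and the remaining clusters
    follow in order of descending overall mean signal (so an
    active-chromatin cluster outranks a signal-poor one); without a
    designated track, clusters are ordered by descending size.  Identical
    inputs and seed give identical labels.
    """
    work = matrix.per_track_scaled() if scale else matrix
    X = work.values
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)

    if repressive_track is not None and repressive_track in matrix.track_labels:
        block = work.track_block(repressive_track)
        rep_mean = np.array([
            block[raw == c].mean() if (raw == c).any() else -np.inf
            for c in range(k)])
        overall = np.array([
            X[raw == c].mean() if (raw == c).any() else -np.inf
            for c in range(k)])
        first = int(np.argmax(rep_mean))
        rest = sorted((c for c in range(k) if c != first),
                      key=lambda c: -overall[c])
        order = np.array([first] + rest)
    else:
        sizes = np.bincount(raw, minlength=k).astype(float)
        norms = np.linalg.norm(km.cluster_centers_, axis=1)
        order = np.argsort(-(sizes + 1e-9 * norms), kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = {pid: relabel[int(c)] for pid, c in zip(matrix.peak_ids, raw)}
    return ClusterAssignment(labels=labels, k=k, seed=seed,
                             inertia=float(km.inertia_))


def cluster_profiles(
    matrix: SignalMatrix,
    assignment: ClusterAssignment,
) -> tuple[dict[int, dict[str, np.ndarray]], dict[int, int]]:
    """Per-cluster, per-track mean bin vectors plus cluster sizes.

    Empty clusters yield an empty profile dict and size 0 (flagged by a
    warning, not an error).
    """
    missing = set(matrix.peak_ids) - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment missing {len(missing)} peaks")
    labels = assignment.label_array(matrix.peak_ids)
    profiles: dict[int, dict[str, np.ndarray]] = {}
    sizes: dict[int, int] = {}
    for c in range(1, assignment.k + 1):
        members = labels == c
        sizes[c] = int(members.sum())
        if sizes[c] == 0:
            logger.warning("cluster %d is empty", c)
            profiles[c] = {}
            continue
        profiles[c] = {
            t: matrix.track_block(t)[members].mean(axis=0)
            for t in matrix.track_labels
        }
    return profiles, sizes


def superimpose_track(
    matrix: SignalMatrix,
    assignment: ClusterAssignment,
    new_track: CoverageTrack,
) -> dict[int, np.ndarray]:
    """Per-cluster mean profile of a new track under the *retained* clustering.

    The clustering is not recomputed; the new track is windowed with the
    original peaks, window, and bin count.
    """
    if set(matrix.peak_ids) != set(assignment.labels):
        raise ValueError("peak set mismatch between matrix and assignment")
    sub = compute_signal_matrix(matrix.peaks, [new_track],
                                window=matrix.window, n_bins=matrix.n_bins)
    sub.peak_ids = matrix.peak_ids  # identity is positional
    profiles, _ = cluster_profiles(sub, assignment)
    return {c: prof.get(new_track.label, np.array([])) for c, prof in profiles.items()}


def profiles_to_frame(profiles: dict[int, dict[str, np.ndarray]],
                      sizes: dict[int, int]) -> pd.DataFrame:
    """Flatten profiles into a tidy frame (cluster, track, bin, mean, size)."""
    rows = []
    for c, tracks in profiles.items():
        for t, vec in tracks.items():
            for b, v in enumerate(vec):
                rows.append((c, t, b, float(v), sizes[c]))
    return pd.DataFrame(rows, columns=["cluster", "track", "bin", "mean", "size"])
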