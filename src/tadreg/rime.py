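"""Spectral-count interactor filtering for RIME/AP-MS experiments.

The filter removes common contaminants (CRAPome frequency above a cutoff),
ribosomal proteins, and any protein with a zero spectral count in any
replicate, then keeps proteins whose replicate-mean spectral count strictly
exceeds a threshold.  Output is ranked by mean count (ties broken by
protein id) so the list is deterministic.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

META_COLUMNS = ("crapome_frequency", "is_ribosomal")


def load_spectral_counts(
    counts_path: str | Path,
    crapome_path: str | Path | None = None,
    ribosomal_path: str | Path | None = None,
) -> pd.DataFrame:
    """Assemble a spectral-count table from TSVs.

    ``counts_path``: protein_id + one integer column per experiment.
    ``crapome_path``: protein_id, crapome_frequency in [0, 1] (missing
    proteins get 0).  ``ribosomal_path``: one protein id per line.
    """
    df = pd.read_csv(counts_path, sep="\t").set_index("protein_id")
    if crapome_path is not None:
        cra = pd.read_csv(crapome_path, sep="\t").set_index("protein_id")
        df["crapome_frequency"] = cra["crapome_frequency"].reindex(df.index).fillna(0.0)
    elif "crapome_frequency" not in df.columns:
        df["crapome_frequency"] = 0.0
    if ribosomal_path is not None:
        ribo = {l.strip() for l in Path(ribosomal_path).read_text().splitlines() if l.strip()}
        df["is_ribosomal"] = df.index.isin(ribo)
    elif "is_ribosomal" not in df.columns:
        df["is_ribosomal"] = False
    return df


def experiment_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def filter_interactors(
    table: pd.DataFrame,
    crapome_max: float = 0.5,
    min_avg: float = 4.0,
) -> pd.DataFrame:
    """Apply the four-rule interactor filter and rank the survivors.

    Removal rules: crapome_frequency > ``crapome_max``; ribosomal; zero
    count in any experiment.  Inclusion rule: mean count strictly >
    ``min_avg``.  Returns the kept rows with a ``mean_count`` column, sorted
    by mean descending, ties by protein id.
    """
    exp_cols = experiment_columns(table)
    if not exp_cols:
        raise ValueError("no experiment columns present")
    counts = table[exp_cols]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative spectral counts")
    if not ((table["crapome_frequency"] >= 0) & (table["crapome_frequency"] <= 1)).all():
        raise ValueError("crapome_frequency outside [0, 1]")

    keep = (
        (table["crapome_frequency"] <= crapome_max)
        & (~table["is_ribosomal"].astype(bool))
        & (counts > 0).all(axis=1)
        & (counts.mean(axis=1) > min_avg)
    )
    out = table.loc[keep].copy()
    out["mean_count"] = counts.loc[keep].mean(axis=1)
    # stable two-key sort: protein id ascending breaks mean-count ties
    out = out.sort_index(kind="stable")
    return out.sort_values("mean_count", ascending=False, kind="stable")
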