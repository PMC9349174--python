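"""Chromatin-state clustering of genomic bins.

Bins with both H3K36me2 and H3K36me3 enrichment ratios in the control
sample are grouped into k clusters (k=5 by default) by k-means on the
log2 ratios.  Labels are relabeled canonically — cluster 1 has the
highest mean log2 me3, descending, ties broken by ascending me2 — and
the fit is permutation-invariant: k-means runs on a lexicographically
sorted copy of the features, so shuffling bin order cannot change any
bin's final label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .chip import EnrichmentTrack
from .genome import BinGrid


@dataclass
class ClusterAssignment:
    grid: BinGrid
    labels: np.ndarray  # float array: 1..k, NaN where unassigned
    k: int

    def present(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    def sizes(self) -> dict[int, int]:
        lab = self.labels[self.present()].astype(int)
        return {c: int(np.sum(lab == c)) for c in range(1, self.k + 1)}


def cluster_bins(
    me2: EnrichmentTrack,
    me3: EnrichmentTrack,
    k: int = 5,
    seed: int = 0,
    n_init: int = 25,
) -> ClusterAssignment:
    """k-means on (log2 me2, log2 me3) over bins where both ratios exist."""
    if me2.grid is not me3.grid and not me2.grid.df.equals(me3.grid.df):
        raise ValueError("me2 and me3 tracks on different grids")
    mask = me2.present() & me3.present()
    X = np.column_stack([np.log2(me2.ratio[mask]), np.log2(me3.ratio[mask])])
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(
            f"degenerate input: fewer than {k} distinct (me2, me3) points"
        )
    # fit on sorted rows so the model is independent of bin order
    order = np.lexsort((X[:, 1], X[:, 0]))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X[order])
    raw = km.predict(X)
    # canonical relabeling: 1 = highest mean me3; ties by ascending me2
    me3_means = np.array([X[raw == c, 1].mean() if (raw == c).any() else -np.inf for c in range(k)])
    me2_means = np.array([X[raw == c, 0].mean() if (raw == c).any() else np.inf for c in range(k)])
    rank_order = np.lexsort((me2_means, -me3_means))
    relabel = np.empty(k, dtype=int)
    for new, old in enumerate(rank_order, start=1):
        relabel[old] = new
    labels = np.full(me2.grid.n_bins, np.nan)
    labels[mask] = relabel[raw]
    return ClusterAssignment(me2.grid, labels, k)


def cluster_summary(
    assignment: ClusterAssignment, tracks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-cluster bin count and mean of each track (NaN-aware)."""
    rows = []
    for c in range(1, assignment.k + 1):
        sel = assignment.labels == c
        row: dict = {"cluster": c, "n": int(sel.sum())}
        for name, values in tracks.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (assignment.grid.n_bins,):
                raise ValueError(f"track {name!r} not aligned to the bin grid")
            vals = values[sel]
            vals = vals[~np.isnan(vals)]
            row[f"mean_{name}"] = float(vals.mean()) if vals.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def export_heatmap_matrix(
    assignment: ClusterAssignment,
    tracks: dict[str, np.ndarray],
    path=None,
) -> pd.DataFrame:
    """Labeled bins as a flat matrix sorted by (cluster, chromosome, start).

    One row per labeled bin, one column per track; stable order across
    runs.  When ``path`` is given the matrix is also written as TSV.
    """
    mask = assignment.present()
    df = assignment.grid.df.loc[mask, ["chrom", "start", "end"]].copy()
    df["cluster"] = assignment.labels[mask].astype(int)
    for name, values in tracks.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (assignment.grid.n_bins,):
            raise ValueError(f"track {name!r} not aligned to the bin grid")
        df[name] = values[mask]
    chrom_order = {c: i for i, c in enumerate(assignment.grid.layout.names)}
    df["_chrom_rank"] = df["chrom"].map(chrom_order)
    df = df.sort_values(["cluster", "_chrom_rank", "start"], kind="mergesort")
    df = df.drop(columns="_chrom_rank").reset_index(drop=True)
    if path is not None:
        from .io import write_table

        write_table(df, path)
    return df
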