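"""Joint effect clustering, cross-species divergence and ATAC enrichment.

Three downstream summaries of the per-gene dynamic effects:

* joint clustering of bin-wise effect-size trajectories — cis (|AI_F1-0.5|),
  differential expression (|AI_F0-0.5|) and trans (|AI_F1-AI_F0|) — for all
  genes with a dynamic call, smoothed (5-bin moving average) and min-max
  scaled, pooled across effect kinds (a gene may contribute several rows);
* transcriptional divergence per cell type from pairwise Spearman
  correlations of log expression between reference-strain cells and between
  reference and other-species cells;
* enrichment of allelic imbalance in linked chromatin-accessibility peaks,
  against a null that shuffles peak AI values across peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

EFFECT_KINDS = ("cis", "trans", "de")


@dataclass
class EffectTrajectory:
    gene: str
    effect_kind: str        # cis / trans / de
    magnitude: np.ndarray   # per-bin effect size, >= 0
    smoothed: np.ndarray
    scaled: np.ndarray      # min-max scaled to [0, 1]


def _moving_average(x, window=5):
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def minmax_scale(x):
    """Scale to [0, 1]; idempotent and order-preserving. Flat input -> zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def make_effect_trajectory(gene, effect_kind, per_bin_magnitude, window=5):
    mag = np.maximum(np.nan_to_num(np.asarray(per_bin_magnitude, dtype=float)), 0.0)
    smooth = _moving_average(mag, window)
    return EffectTrajectory(str(gene), effect_kind, mag, smooth, minmax_scale(smooth))


def effect_trajectories_from_pairs(pairs, calls: pd.DataFrame, window=5):
    """Build effect trajectories for all genes with dynamic calls.

    calls : output of :func:`allelicdyn.transgp.bayes_factor_table`; a gene
    contributes a cis row if ``call_dynamic_cis``, a trans row if
    ``call_dynamic_trans`` and a de row if ``call_dynamic_de``.
    """
    by_gene = {p.gene: p for p in pairs}
    trajs = []
    for _, row in calls.iterrows():
        pair = by_gene.get(row["gene"])
        if pair is None:
            continue
        ai_f1 = np.where(pair.mask_f1, pair.y_f1, np.nan)
        ai_f0 = np.where(pair.mask_f0, pair.y_f0, np.nan)
        if row.get("call_dynamic_cis", False):
            trajs.append(make_effect_trajectory(pair.gene, "cis",
                                                np.abs(ai_f1 - 0.5), window))
        if row.get("call_dynamic_trans", False):
            trajs.append(make_effect_trajectory(pair.gene, "trans",
                                                np.abs(ai_f1 - ai_f0), window))
        if row.get("call_dynamic_de", False):
            trajs.append(make_effect_trajectory(pair.gene, "de",
                                                np.abs(ai_f0 - 0.5), window))
    return trajs


def joint_effect_clustering(trajectories, n_clusters: int):
    """Ward clustering of pooled scaled effect trajectories.

    Returns (table, cluster_kind_means, aggregate) where table has one row
    per (gene, effect_kind) with its cluster label, cluster_kind_means maps
    (cluster, kind) -> mean scaled profile, and aggregate is the unscaled
    per-bin mean effect size over all input trajectories.
    """
    trajs = list(trajectories)
    if len(trajs) < n_clusters:
        raise ValueError("fewer trajectories than requested clusters")
    X = np.vstack([tr.scaled for tr in trajs])
    link = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(link, t=n_clusters, criterion="maxclust") - 1
    table = pd.DataFrame({
        "gene": [tr.gene for tr in trajs],
        "effect_kind": [tr.effect_kind for tr in trajs],
        "cluster": labels,
    })
    means = {}
    for c in range(labels.max() + 1):
        for kind in EFFECT_KINDS:
            sel = (labels == c) & (table["effect_kind"] == kind).to_numpy()
            if sel.any():
                means[(c, kind)] = X[sel].mean(axis=0)
    aggregate = np.vstack([tr.magnitude for tr in trajs]).mean(axis=0)
    return table, means, aggregate


# ---------------------------------------------------------------------------
# cross-species correlation divergence


def _pairwise_spearman(A, B=None):
    """Spearman correlations across genes for pairs of cells (columns).

    A, B : genes x cells matrices of log expression. With B None, within-A
    unordered pairs; otherwise all cross pairs.
    """
    ra = np.apply_along_axis(rankdata, 0, A)
    ra = (ra - ra.mean(axis=0)) / np.maximum(ra.std(axis=0), 1e-12)
    if B is None:
        C = (ra.T @ ra) / A.shape[0]
        iu = np.triu_indices(A.shape[1], k=1)
        return C[iu]
    rb = np.apply_along_axis(rankdata, 0, B)
    rb = (rb - rb.mean(axis=0)) / np.maximum(rb.std(axis=0), 1e-12)
    return ((ra.T @ rb) / A.shape[0]).ravel()


def correlation_divergence(expr_by_species: dict, cell_types_by_species: dict,
                           reference: str = "B6", max_cells_per_group: int = 200,
                           seed: int = 0) -> pd.DataFrame:
    """Per-cell-type transcriptional divergence from the reference species.

    expr_by_species : species -> (genes x cells) log expression matrix on a
        shared gene set; cell_types_by_species : species -> per-cell labels.
    Divergence of a species at a cell type is
    ``median(within-reference pair correlations) - median(cross pairs)``.
    Groups larger than ``max_cells_per_group`` are subsampled (seeded).
    Singleton groups yield NaN and are reported.
    """
    rng = np.random.default_rng(seed)
    ref_expr = np.asarray(expr_by_species[reference], dtype=float)
    ref_ct = np.asarray(cell_types_by_species[reference])
    rows = []
    for species, expr in expr_by_species.items():
        if species == reference:
            continue
        expr = np.asarray(expr, dtype=float)
        if expr.shape[0] != ref_expr.shape[0]:
            raise ValueError("species matrices must share the gene set")
        ct = np.asarray(cell_types_by_species[species])
        for cell_type in pd.unique(ref_ct):
            ref_cols = np.flatnonzero(ref_ct == cell_type)
            sp_cols = np.flatnonzero(ct == cell_type)
            if ref_cols.size < 2 or sp_cols.size < 1:
                rows.append({"species": species, "cell_type": cell_type,
                             "divergence": np.nan, "n_ref": ref_cols.size,
                             "n_other": sp_cols.size})
                continue
            if ref_cols.size > max_cells_per_group:
                ref_cols = rng.choice(ref_cols, max_cells_per_group, replace=False)
            if sp_cols.size > max_cells_per_group:
                sp_cols = rng.choice(sp_cols, max_cells_per_group, replace=False)
            within = _pairwise_spearman(ref_expr[:, ref_cols])
            cross = _pairwise_spearman(ref_expr[:, ref_cols], expr[:, sp_cols])
            rows.append({
                "species": species, "cell_type": cell_type,
                "divergence": float(np.median(within) - np.median(cross)),
                "n_ref": ref_cols.size, "n_other": sp_cols.size,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ATAC allelic-imbalance enrichment


def filter_peaks(peak_table: pd.DataFrame, min_mean_reads: float = 50.0,
                 max_distance_bp: float = 20_000.0) -> pd.DataFrame:
    """Depth and peak-gene distance filters for the peak AI table."""
    keep = (peak_table["mean_allelic_reads"] >= min_mean_reads) & \
        (peak_table["distance_bp"] <= max_distance_bp)
    return peak_table.loc[keep].reset_index(drop=True)


def atac_enrichment(peak_table: pd.DataFrame, gene_ai: pd.DataFrame,
                    d_threshold: float = 0.1, n_shuffles: int = 1000,
                    seed: int = 0):
    """Enrichment of peak allelic imbalance at genes with expression AI.

    gene_ai : DataFrame with columns ``gene`` and ``ai`` (expression allelic
    ratio). Genes with a linked peak are ranked by expression effect size
    ``d = |AI - 0.5|`` into deciles; the enrichment curve is the per-decile
    fraction of linked peaks with peak-level d above ``d_threshold``. The
    test statistic is that fraction in the top decile; the permutation null
    shuffles observed peak AI values across peaks;
    ``p = (1 + #{null >= observed}) / (1 + n_shuffles)``.

    Returns (curve: DataFrame, p_value, observed_fraction).
    """
    if n_shuffles < 100:
        import warnings
        warnings.warn("fewer than 100 shuffles gives a coarse permutation p-value")
    rng = np.random.default_rng(seed)
    merged = peak_table.merge(gene_ai[["gene", "ai"]].rename(columns={"ai": "gene_ai"}),
                              on="gene", how="inner")
    merged = merged.loc[merged["gene_ai"].notna() & merged["ai"].notna()].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no peaks could be linked to genes with expression AI")
    merged["gene_d"] = (merged["gene_ai"] - 0.5).abs()
    merged["peak_d"] = (merged["ai"] - 0.5).abs()
    ranks = rankdata(merged["gene_d"].to_numpy(), method="ordinal") - 1
    decile = np.minimum((10 * ranks / len(merged)).astype(int), 9)
    merged["decile"] = decile + 1

    hit = (merged["peak_d"] > d_threshold).to_numpy()
    curve = merged.assign(hit=hit).groupby("decile")["hit"].mean().rename("fraction").reset_index()
    top = decile == 9
    observed = float(hit[top].mean())

    peak_d = merged["peak_d"].to_numpy()
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = (rng.permutation(peak_d)[top] > d_threshold).mean()
    p = float((1 + np.sum(null >= observed)) / (1 + n_shuffles))
    return curve, p, observed
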