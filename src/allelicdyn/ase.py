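"""Allelic ratios, fold changes, per-cell imbalance scores and QC flags.

Allele-specific expression is summarised either as an allelic ratio
``AI = B6 / (B6 + CAST)`` or as a log2 allelic fold change
``aFC = log2(B6 / CAST)``; the two are linked by ``AI = 1 / (1 + 2**-aFC)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from .datamodel import AllelicCountMatrix


def _pooled_counts(acm: AllelicCountMatrix, mask):
    cols = np.flatnonzero(np.asarray(mask))
    b6 = np.asarray(acm.layer_b6[:, cols].sum(axis=1)).ravel()
    cast = np.asarray(acm.layer_cast[:, cols].sum(axis=1)).ravel()
    return b6, cast


def _afc(b6, cast):
    """log2(B6/CAST) with a 0.5 pseudocount on both alleles only when either
    pooled count is zero (keeps the fold change finite; the raw ratio is
    never pseudocounted)."""
    b6 = b6.astype(float).copy()
    cast = cast.astype(float).copy()
    zero = (b6 == 0) | (cast == 0)
    b6[zero] += 0.5
    cast[zero] += 0.5
    return np.log2(b6 / cast)


def allelic_summary(acm: AllelicCountMatrix, cells: pd.DataFrame, group_by=None):
    """Pseudo-bulk allelic summaries per gene and group.

    group_by : None (one group of all cells) or a cells-table column name
        (e.g. "cell_type", "sample").

    Returns a DataFrame with columns gene, scope, ai, afc_log2, depth. Groups
    with zero allelic depth for a gene yield NaN ratios (undefined, not 0.5).
    """
    if group_by is None:
        groups = {"all": np.ones(len(cells), dtype=bool)}
    else:
        col = cells[group_by]
        groups = {str(v): (col == v).to_numpy() for v in pd.unique(col)}
    frames = []
    for scope, mask in groups.items():
        if not mask.any():
            raise ValueError(f"empty group '{scope}'")
        b6, cast = _pooled_counts(acm, mask)
        depth = b6 + cast
        with np.errstate(invalid="ignore", divide="ignore"):
            ai = np.where(depth > 0, b6 / np.maximum(depth, 1), np.nan)
        afc = np.where(depth > 0, _afc(b6, cast), np.nan)
        frames.append(pd.DataFrame({
            "gene": acm.genes, "scope": scope, "ai": ai,
            "afc_log2": afc, "depth": depth,
        }))
    return pd.concat(frames, ignore_index=True)


def ai_score_matrix(acm: AllelicCountMatrix) -> sparse.csr_matrix:
    """Per-gene, per-cell allelic-imbalance confidence score.

    The score is the log-likelihood ratio (natural log) of the observed
    allelic counts under the empirical rate k/n versus the balanced rate 0.5:

        score = log Binom(k; n, k/n) - log Binom(k; n, 0.5)
              = k log(k/n) + (n-k) log(1 - k/n) + n log 2

    Zero by definition when no allelic reads were observed; always >= 0. The
    score separates confidence of imbalance from expression level so a
    dimensionality reduction over it reflects allele-specificity, not depth.
    """
    n_mat = (acm.layer_b6 + acm.layer_cast).tocoo()
    n_mat.eliminate_zeros()
    if n_mat.nnz == 0:
        return sparse.csr_matrix(acm.shape)
    n = n_mat.data.astype(float)
    # align b6 entries onto the nonzero pattern of n
    b6_csr = acm.layer_b6.tocsr()
    k = np.asarray(b6_csr[n_mat.row, n_mat.col]).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        term_k = np.where(k > 0, k * np.log(k / n), 0.0)
        term_nk = np.where(n - k > 0, (n - k) * np.log(1.0 - k / n), 0.0)
    score = term_k + term_nk + n * np.log(2.0)
    score = np.maximum(score, 0.0)  # clip tiny negative rounding noise
    return sparse.csr_matrix((score, (n_mat.row, n_mat.col)), shape=acm.shape)


def qc_allelic_flags(acm: AllelicCountMatrix, cells: pd.DataFrame, genes: pd.DataFrame,
                     maternal_chroms=("MT", "X"),
                     f1_bias_threshold: float = 0.2,
                     f0_balance_threshold: float = 0.1) -> pd.DataFrame:
    """Flag likely allelic-mapping artifacts in the gene table.

    Two patterns are flagged (flags are additive to any existing ones):

    ``mt_x_excluded``
        mitochondrial / X-linked genes whose reads map exclusively to the
        reference (maternal) allele in F1 cells.
    ``paternal_bias_artifact``
        genes with a strong paternal (CAST) bias in F1
        (pooled AI < ``f1_bias_threshold``) but balanced behaviour in the F0
        comparison (|AI_F0 - 0.5| < ``f0_balance_threshold``), the signature
        of reads from one haplotype failing to map.
    """
    genes = genes.copy()
    is_f1 = (cells["genotype"] == "F1").to_numpy()
    b6_f1, cast_f1 = _pooled_counts(acm, is_f1)
    depth_f1 = b6_f1 + cast_f1
    with np.errstate(invalid="ignore"):
        ai_f1 = np.where(depth_f1 > 0, b6_f1 / np.maximum(depth_f1, 1), np.nan)

    # F0 "ratio": B6-sample allelic reads vs CAST-sample allelic reads
    is_b6s = (cells["genotype"] == "F0_B6").to_numpy()
    is_cs = (cells["genotype"] == "F0_CAST").to_numpy()
    b6_tot = _pooled_counts(acm, is_b6s)[0]
    cast_tot = _pooled_counts(acm, is_cs)[1]
    depth_f0 = b6_tot + cast_tot
    with np.errstate(invalid="ignore"):
        ai_f0 = np.where(depth_f0 > 0, b6_tot / np.maximum(depth_f0, 1), np.nan)

    chrom = genes.get("chromosome", pd.Series("", index=genes.index)).astype(str)
    mono_maternal = (depth_f1 > 0) & (cast_f1 == 0) & chrom.isin(maternal_chroms).to_numpy()
    paternal_artifact = (
        (depth_f1 > 0) & (depth_f0 > 0)
        & (ai_f1 < f1_bias_threshold)
        & (np.abs(ai_f0 - 0.5) < f0_balance_threshold)
    )

    flags = genes["flags"].fillna("").astype(str).to_numpy(dtype=object).copy()

    def _add(mask, flag):
        for i in np.flatnonzero(mask):
            current = [f for f in flags[i].split(",") if f]
            if flag not in current:
                current.append(flag)
            flags[i] = ",".join(current)

    _add(mono_maternal, "mt_x_excluded")
    _add(paternal_artifact, "paternal_bias_artifact")
    genes["flags"] = flags
    return genes
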