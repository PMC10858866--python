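"""Shared data model and on-disk interchange format.

An experiment is stored as three Matrix Market coordinate integer matrices
(genes x cells) — ``matrix_b6.mtx`` (B6-allele UMIs), ``matrix_cast.mtx``
(CAST-allele UMIs) and ``matrix_total.mtx`` (all UMIs including those not
assignable to an allele) — plus two tab-separated sidecars:

``genes.tsv``
    columns ``gene``, ``chromosome`` and optional ``flags`` (comma-separated
    subset of {mt_x_excluded, paternal_bias_artifact}).
``cells.tsv``
    columns ``cell``, ``sample``, ``genotype`` (F0_B6 / F0_CAST / F1),
    ``replicate``, ``cell_type``, ``pseudotime`` (in [0, 1]; may be empty for
    somatic cells).

Indices are 0-based in memory and 1-based on disk per the Matrix Market
standard.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

GENOTYPES = ("F0_B6", "F0_CAST", "F1")
GENE_FLAGS = ("mt_x_excluded", "paternal_bias_artifact")

LAYER_FILES = {
    "b6": "matrix_b6.mtx",
    "cast": "matrix_cast.mtx",
    "total": "matrix_total.mtx",
}


@dataclass
class AllelicCountMatrix:
    """Sparse genes x cells UMI counts with two allele layers and a total layer.

    Invariants (checked by :meth:`validate`): all layers share one shape,
    entries are nonnegative integers, and elementwise
    ``b6 + cast <= total``.
    """

    genes: pd.Index
    cells: pd.Index
    layer_b6: sparse.csr_matrix
    layer_cast: sparse.csr_matrix
    layer_total: sparse.csr_matrix

    def __post_init__(self):
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        for name in ("layer_b6", "layer_cast", "layer_total"):
            setattr(self, name, sparse.csr_matrix(getattr(self, name)))

    @property
    def shape(self):
        return (len(self.genes), len(self.cells))

    def layers(self):
        return {"b6": self.layer_b6, "cast": self.layer_cast, "total": self.layer_total}

    def validate(self):
        shape = self.shape
        for name, layer in self.layers().items():
            if layer.shape != shape:
                raise ValueError(
                    f"layer '{name}' has shape {layer.shape}, expected {shape} "
                    f"({len(self.genes)} genes x {len(self.cells)} cells)"
                )
            data = layer.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError(f"layer '{name}' contains negative or non-integer entries")
        excess = (self.layer_b6 + self.layer_cast - self.layer_total).tocoo()
        bad = excess.data > 0
        if np.any(bad):
            i = excess.row[bad][0]
            j = excess.col[bad][0]
            raise ValueError(
                "allelic counts exceed totals: gene "
                f"'{self.genes[i]}', cell '{self.cells[j]}' has "
                "b6 + cast > total"
            )
        return self

    def subset_genes(self, genes):
        idx = self.genes.get_indexer(pd.Index(genes))
        if np.any(idx < 0):
            raise KeyError("unknown gene in subset")
        return AllelicCountMatrix(
            self.genes[idx], self.cells,
            self.layer_b6[idx], self.layer_cast[idx], self.layer_total[idx],
        )

    def subset_cells(self, mask):
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return AllelicCountMatrix(
            self.genes, self.cells[cols],
            self.layer_b6[:, cols], self.layer_cast[:, cols], self.layer_total[:, cols],
        )


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    required = {"cell", "sample", "genotype", "replicate", "cell_type", "pseudotime"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    if cells["cell"].duplicated().any():
        raise ValueError("duplicate cell barcodes")
    bad = ~cells["genotype"].isin(GENOTYPES)
    if bad.any():
        raise ValueError(f"unknown genotype labels: {sorted(cells.loc[bad, 'genotype'].unique())}")
    geno_per_sample = cells.groupby("sample")["genotype"].nunique()
    if (geno_per_sample > 1).any():
        raise ValueError("genotype is not constant within a sample")
    pt = cells["pseudotime"]
    defined = pt.notna()
    if defined.any() and ((pt[defined] < 0) | (pt[defined] > 1)).any():
        raise ValueError("pseudotime outside [0, 1]")
    return cells


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    if "gene" not in genes.columns:
        raise ValueError("genes table missing 'gene' column")
    if "flags" not in genes.columns:
        genes = genes.assign(flags="")
    genes["flags"] = genes["flags"].fillna("")
    for val in genes["flags"]:
        for flag in str(val).split(","):
            if flag and flag not in GENE_FLAGS:
                raise ValueError(f"unknown gene flag '{flag}'")
    return genes


def gene_is_flagged(genes: pd.DataFrame) -> np.ndarray:
    """Boolean mask of genes carrying any exclusion flag."""
    return genes["flags"].fillna("").astype(str).str.len().gt(0).to_numpy()


# ---------------------------------------------------------------------------
# readers / writers


def read_allelic_counts(path):
    """Read an experiment directory -> (AllelicCountMatrix, cells, genes).

    Raises on layer-dimension mismatch (naming the offending layer) and on
    non-integer matrix entries.
    """
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", dtype={"gene": str})
    genes = validate_gene_table(genes)
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", dtype={"cell": str, "sample": str})
    cells = validate_cell_table(cells)

    layers = {}
    expected = (len(genes), len(cells))
    for name, fname in LAYER_FILES.items():
        mat = sparse.csr_matrix(spio.mmread(os.path.join(path, fname)))
        if mat.shape != expected:
            raise ValueError(
                f"layer '{name}' ({fname}) has shape {mat.shape} but annotation "
                f"tables imply {expected}"
            )
        layers[name] = mat
    acm = AllelicCountMatrix(
        genes["gene"], cells["cell"], layers["b6"], layers["cast"], layers["total"]
    ).validate()
    return acm, cells, genes


def write_allelic_counts(path, acm: AllelicCountMatrix, cells: pd.DataFrame, genes: pd.DataFrame):
    """Write the experiment in the interchange format (round-trips exactly)."""
    os.makedirs(path, exist_ok=True)
    acm.validate()
    for name, fname in LAYER_FILES.items():
        mat = acm.layers()[name].tocoo()
        mat = sparse.coo_matrix((mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape)
        spio.mmwrite(os.path.join(path, fname), mat, field="integer")
    genes.to_csv(os.path.join(path, "genes.tsv"), sep="\t", index=False)
    cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters and downsampling


def allelic_depth_per_sample(acm: AllelicCountMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample summed allelic (b6 + cast) reads."""
    allelic = acm.layer_b6 + acm.layer_cast
    samples = cells["sample"].to_numpy()
    labels = pd.unique(samples)
    out = np.zeros((acm.shape[0], len(labels)), dtype=np.int64)
    for j, s in enumerate(labels):
        cols = np.flatnonzero(samples == s)
        out[:, j] = np.asarray(allelic[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=acm.genes, columns=labels)


def filter_genes_by_allelic_depth(acm, cells, min_reads_per_sample, genes=None):
    """Genes whose allelic reads strictly exceed the threshold in EVERY sample.

    Genes carrying an exclusion flag in ``genes`` are removed regardless of
    depth. Returns a pandas Index (possibly empty).
    """
    if min_reads_per_sample < 0:
        raise ValueError("min_reads_per_sample must be >= 0")
    depth = allelic_depth_per_sample(acm, cells)
    keep = (depth > min_reads_per_sample).all(axis=1)
    if genes is not None:
        flagged = pd.Index(genes.loc[gene_is_flagged(genes), "gene"])
        keep &= ~depth.index.isin(flagged)
    return depth.index[keep]


def downsample_f0(acm: AllelicCountMatrix, cells: pd.DataFrame, fraction: float, seed: int):
    """Binomially thin every count in F0 cells at rate ``fraction``.

    Emulates read downsampling of the parental libraries so that per-allele
    coverage matches the F1 libraries (each F1 allele receives roughly half
    the library's reads). F1 cells are untouched. Deterministic given seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return acm
    rng = np.random.default_rng(seed)
    is_f0_col = cells["genotype"].isin(("F0_B6", "F0_CAST")).to_numpy()

    # Thin the three disjoint read categories (b6, cast, unassigned); each
    # layer entry is then Binomial(count, fraction) marginally while
    # b6 + cast <= total is preserved exactly.
    def _thin(mat):
        coo = mat.tocoo()
        data = coo.data.astype(np.int64).copy()
        sel = is_f0_col[coo.col]
        data[sel] = rng.binomial(data[sel], fraction)
        return sparse.csr_matrix((data, (coo.row, coo.col)), shape=mat.shape)

    unassigned = acm.layer_total - acm.layer_b6 - acm.layer_cast
    b6 = _thin(acm.layer_b6)
    cast = _thin(acm.layer_cast)
    total = b6 + cast + _thin(unassigned)
    return AllelicCountMatrix(acm.genes, acm.cells, b6, cast, total)
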