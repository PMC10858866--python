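"""Synthetic F0/F1 single-cell allele-specific datasets with known truth.

The generator emulates the hybrid-cross design used to separate cis- from
trans-acting regulatory change: two inbred parental strains (B6, CAST) and
their F1 offspring are profiled along one differentiation trajectory. A
cis-effect c(t) shifts the allelic ratio inside F1 cells (logit2 of the
B6-allele rate equals c); a trans-effect delta(t) additionally shifts the
between-strain expression ratio of the parents, so the F0 log2 ratio is
c(t) + delta(t) while the F1 ratio tracks c(t) alone. Either effect may be
constant ("persistent") or vary along pseudotime ("dynamic").

Per-cell totals are negative-binomially overdispersed (var = mu + phi mu^2)
around a library-scaled expression profile lambda(t); only a fixed fraction
of reads is allele-informative; F1 allelic counts are beta-binomial around
the latent rate. Post-meiotic (haploid) cells are treated like diploid cells,
mirroring the chromatoid-body RNA sharing that keeps spermatid expression
effectively biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .datamodel import AllelicCountMatrix, validate_cell_table, validate_gene_table

CELL_TYPE_CUTS = (0.25, 0.5, 0.75)
CELL_TYPE_LABELS = ("SG", "SC", "RS", "ES")  # spermatogonia ... elongating spermatids

TRAJECTORY_SHAPES = ("logistic_step", "sine", "ramp")
EXPRESSION_SHAPES = ("constant", "bump", "ramp_up", "ramp_down")


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults reflect the real design this emulates: six libraries per
    genotype class is the full cross (2 B6 + 2 CAST + 2 F1 mice per batch,
    three batches -> 6 each), about a quarter of reads carry an
    allele-informative SNP, and effect sizes of one log2 unit.
    """

    n_genes: int = 200
    n_cells_per_sample: int = 200
    n_replicates_per_genotype: int = 6
    depth_mean: float = 20.0          # mean total UMIs per cell and gene
    nb_dispersion: float = 0.15       # phi, var = mu + phi mu^2
    bb_overdispersion: float = 0.02   # rho, intra-class correlation of allelic counts
    fraction_dynamic_cis: float = 0.0
    fraction_persistent_cis: float = 0.0
    fraction_persistent_trans: float = 0.0
    fraction_dynamic_trans: float = 0.0
    effect_size_log2: float = 1.0
    trajectory_family: tuple = TRAJECTORY_SHAPES
    seed: int = 0
    # secondary knobs
    frac_assignable: float = 0.2582   # fraction of reads informative for an allele
    library_scale_sd: float = 0.2     # lognormal sd of per-library depth factors
    fraction_dynamic_expression: float = 0.0  # genes with non-constant lambda(t)

    def __post_init__(self):
        f_cis = self.fraction_dynamic_cis + self.fraction_persistent_cis
        f_trans = self.fraction_dynamic_trans + self.fraction_persistent_trans
        for name, val in (("cis", f_cis), ("trans", f_trans)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} effect fractions must sum to within [0, 1]")
        if self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth_mean and nb_dispersion must be positive")
        if not 0.0 <= self.bb_overdispersion < 1.0:
            raise ValueError("bb_overdispersion must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-gene generating truth: category, dynamics and latent profiles."""

    table: pd.DataFrame                 # gene, category, cis_dynamic, trans_dynamic, shapes
    cis_profiles: list = field(repr=False, default_factory=list)    # t -> log2 aFC in F1
    trans_profiles: list = field(repr=False, default_factory=list)  # t -> extra F0 log2 FC
    expression_profiles: list = field(repr=False, default_factory=list)  # t -> mean scale

    def category(self):
        return self.table.set_index("gene")["category"]


# ---------------------------------------------------------------------------
# profile construction


def _constant(value):
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


def _make_shape(name, amplitude, rng, params=None):
    """A dynamic profile of the named family with the given peak amplitude.

    ``params`` optionally pins the otherwise randomly drawn shape
    parameters (``sign``; ``t0`` for the step, ``phase`` for the sine) so a
    family member can be planted as a coherent, clusterable shape.
    """
    params = params or {}
    sign = params.get("sign", rng.choice((-1.0, 1.0)))
    a = sign * amplitude
    if name == "logistic_step":
        # punctuated switch, mimicking abrupt regime changes such as the
        # entry into meiosis or the histone-to-protamine transition
        t0 = params.get("t0", rng.uniform(0.25, 0.75))
        return lambda t, a=a, t0=t0: a * (1.0 / (1.0 + np.exp(-(np.asarray(t) - t0) / 0.05)) - 0.5)
    if name == "sine":
        phase = params.get("phase", rng.uniform(0, 2 * np.pi))
        return lambda t, a=a, phase=phase: a * np.sin(2 * np.pi * np.asarray(t) + phase)
    if name == "ramp":
        return lambda t, a=a: a * (2.0 * np.asarray(t, dtype=float) - 1.0)
    raise ValueError(f"unknown trajectory shape '{name}'")


def _make_expression(name, rng):
    if name == "constant":
        return _constant(1.0), "constant"
    if name == "bump":
        t0 = rng.uniform(0.3, 0.7)
        w = rng.uniform(0.08, 0.2)
        def f(t, t0=t0, w=w):
            x = np.exp(-0.5 * ((np.asarray(t) - t0) / w) ** 2)
            return 0.2 + 1.6 * x
        return f, "bump"
    if name == "ramp_up":
        return lambda t: 0.25 + 1.5 * np.asarray(t, dtype=float), "ramp_up"
    if name == "ramp_down":
        return lambda t: 1.75 - 1.5 * np.asarray(t, dtype=float), "ramp_down"
    raise ValueError(f"unknown expression shape '{name}'")


def _largest_remainder(fractions, total):
    """Integer counts summing to ``total`` proportional to ``fractions``."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def assign_categories(cfg: SimConfig, rng) -> pd.DataFrame:
    """Deterministic per-gene category assignment.

    cis and trans effects are allocated as if independent: the joint fractions
    are products of the marginal cis/trans fractions, converted to exact
    counts by largest-remainder rounding and assigned via a seeded
    permutation. Within each effect, dynamic vs persistent follows the ratio
    of the corresponding config fractions.
    """
    n = cfg.n_genes
    f_cis = cfg.fraction_dynamic_cis + cfg.fraction_persistent_cis
    f_trans = cfg.fraction_dynamic_trans + cfg.fraction_persistent_trans
    joint = [
        (1 - f_cis) * (1 - f_trans),  # conserved
        f_cis * (1 - f_trans),        # cis
        (1 - f_cis) * f_trans,        # trans
        f_cis * f_trans,              # cis+trans
    ]
    counts = _largest_remainder(joint, n)
    labels = np.repeat(["conserved", "cis", "trans", "cis+trans"], counts)
    perm = rng.permutation(n)
    category = np.empty(n, dtype=object)
    category[perm] = labels

    has_cis = np.isin(category, ("cis", "cis+trans"))
    has_trans = np.isin(category, ("trans", "cis+trans"))

    def _dynamic_flags(mask, frac_dynamic, frac_total):
        flags = np.zeros(n, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size and frac_total > 0:
            n_dyn = int(round(idx.size * frac_dynamic / frac_total))
            chosen = rng.permutation(idx)[:n_dyn]
            flags[chosen] = True
        return flags

    cis_dynamic = _dynamic_flags(has_cis, cfg.fraction_dynamic_cis, f_cis)
    trans_dynamic = _dynamic_flags(has_trans, cfg.fraction_dynamic_trans, f_trans)
    return pd.DataFrame({
        "gene": [f"gene{i:05d}" for i in range(n)],
        "category": category,
        "has_cis": has_cis,
        "has_trans": has_trans,
        "cis_dynamic": cis_dynamic,
        "trans_dynamic": trans_dynamic,
    })


def build_truth(cfg: SimConfig, rng) -> GroundTruth:
    table = assign_categories(cfg, rng)
    # family entries are shape names or (name, fixed-parameter dict) pairs
    family = [(e, None) if isinstance(e, str) else (e[0], dict(e[1]))
              for e in cfg.trajectory_family]
    cis_profiles, trans_profiles, expr_profiles = [], [], []
    cis_shapes, trans_shapes, expr_shapes = [], [], []

    n_dyn_expr = int(round(cfg.fraction_dynamic_expression * cfg.n_genes))
    dyn_expr = np.zeros(cfg.n_genes, dtype=bool)
    dyn_expr[rng.permutation(cfg.n_genes)[:n_dyn_expr]] = True

    for i, row in table.iterrows():
        if row.has_cis:
            if row.cis_dynamic:
                shape, sp = family[rng.integers(len(family))]
                cis_profiles.append(_make_shape(shape, cfg.effect_size_log2, rng, sp))
                cis_shapes.append(shape)
            else:
                sign = rng.choice((-1.0, 1.0))
                cis_profiles.append(_constant(sign * cfg.effect_size_log2))
                cis_shapes.append("constant")
        else:
            cis_profiles.append(_constant(0.0))
            cis_shapes.append("none")
        if row.has_trans:
            if row.trans_dynamic:
                shape, sp = family[rng.integers(len(family))]
                trans_profiles.append(_make_shape(shape, cfg.effect_size_log2, rng, sp))
                trans_shapes.append(shape)
            else:
                sign = rng.choice((-1.0, 1.0))
                trans_profiles.append(_constant(sign * cfg.effect_size_log2))
                trans_shapes.append("constant")
        else:
            trans_profiles.append(_constant(0.0))
            trans_shapes.append("none")
        if dyn_expr[i]:
            shape = EXPRESSION_SHAPES[1 + rng.integers(3)]
            f, nm = _make_expression(shape, rng)
        else:
            f, nm = _make_expression("constant", rng)
        expr_profiles.append(f)
        expr_shapes.append(nm)

    table = table.assign(cis_shape=cis_shapes, trans_shape=trans_shapes,
                         expression_shape=expr_shapes)
    return GroundTruth(table, cis_profiles, trans_profiles, expr_profiles)


# ---------------------------------------------------------------------------
# sampling


def _rnb(rng, mean, phi):
    """Negative binomial via gamma-Poisson mixture; var = mean + phi mean^2."""
    mean = np.maximum(mean, 1e-12)
    if phi < 1e-10:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def _rbb(rng, n, p, rho):
    """Beta-binomial; rho -> 0 degenerates to binomial."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if rho < 1e-10:
        return rng.binomial(n, np.broadcast_to(p, n.shape))
    s = (1.0 - rho) / rho
    q = rng.beta(np.maximum(p * s, 1e-9), np.maximum((1 - p) * s, 1e-9), size=n.shape)
    return rng.binomial(n, q)


def logit2_inv(c):
    """Map log2 allelic fold change to the B6-allele rate: 1 / (1 + 2^-c)."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(c, dtype=float)))


def simulate_experiment(cfg: SimConfig):
    """Generate one experiment. Returns (acm, cells, genes, truth).

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = build_truth(cfg, rng)

    # --- cells -------------------------------------------------------------
    rows = []
    for genotype in ("F0_B6", "F0_CAST", "F1"):
        for rep in range(1, cfg.n_replicates_per_genotype + 1):
            sample = f"{genotype}_rep{rep}"
            pt = rng.uniform(0.0, 1.0, size=cfg.n_cells_per_sample)
            ct = np.asarray(CELL_TYPE_LABELS)[np.searchsorted(CELL_TYPE_CUTS, pt)]
            for j in range(cfg.n_cells_per_sample):
                rows.append((f"{sample}_c{j:04d}", sample, genotype, rep, ct[j], pt[j]))
    cells = pd.DataFrame(rows, columns=["cell", "sample", "genotype", "replicate",
                                        "cell_type", "pseudotime"])
    n_cells = len(cells)
    samples = pd.unique(cells["sample"])
    lib_scale = dict(zip(samples, np.exp(rng.normal(0.0, cfg.library_scale_sd, len(samples)))))
    cell_scale = cells["sample"].map(lib_scale).to_numpy()
    t = cells["pseudotime"].to_numpy()
    genotype = cells["genotype"].to_numpy()
    is_f1 = genotype == "F1"
    is_b6 = genotype == "F0_B6"
    is_cast = genotype == "F0_CAST"

    # --- per-gene latent values on cells ------------------------------------
    n_genes = cfg.n_genes
    c_mat = np.empty((n_genes, n_cells))
    d_mat = np.empty((n_genes, n_cells))
    lam = np.empty((n_genes, n_cells))
    for g in range(n_genes):
        c_mat[g] = truth.cis_profiles[g](t)
        d_mat[g] = truth.trans_profiles[g](t)
        lam[g] = truth.expression_profiles[g](t)

    # F0 strain-specific expression: log2(B6/CAST) = c + delta, split
    # symmetrically around the shared profile
    shift = np.exp2(0.5 * (c_mat + d_mat))
    mean = cfg.depth_mean * lam * cell_scale[None, :]
    mean[:, is_b6] *= shift[:, is_b6]
    mean[:, is_cast] /= shift[:, is_cast]

    total = _rnb(rng, mean, cfg.nb_dispersion)
    assignable = rng.binomial(total, cfg.frac_assignable)

    b6 = np.zeros_like(total)
    cast = np.zeros_like(total)
    b6[:, is_b6] = assignable[:, is_b6]
    cast[:, is_cast] = assignable[:, is_cast]
    p1 = logit2_inv(c_mat[:, is_f1])
    k = _rbb(rng, assignable[:, is_f1], p1, cfg.bb_overdispersion)
    b6[:, is_f1] = k
    cast[:, is_f1] = assignable[:, is_f1] - k

    acm = AllelicCountMatrix(
        truth.table["gene"], cells["cell"],
        sparse.csr_matrix(b6), sparse.csr_matrix(cast), sparse.csr_matrix(total),
    )
    genes = pd.DataFrame({
        "gene": truth.table["gene"],
        "chromosome": "autosome",
        "flags": "",
    })
    validate_cell_table(cells)
    validate_gene_table(genes)
    return acm, cells, genes, truth


def simulate_peak_table(truth: GroundTruth, n_peaks: int, coupling: float, seed: int,
                        mean_reads: float = 100.0, rho_peak: float = 0.02,
                        n_replicates: int = 2):
    """Synthetic allele-specific chromatin-accessibility peaks linked to genes.

    With probability ``coupling`` a peak's allelic rate is centred on its
    gene's (pseudotime-averaged) cis-driven allelic rate, otherwise on 0.5.
    Replicate-level allelic reads are beta-binomial. Peak-gene distances are
    drawn within the 20 kb linkage window.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.table["gene"].to_numpy()
    gidx = rng.integers(len(genes), size=n_peaks)
    grid = np.linspace(0.0, 1.0, 101)
    gene_rate = np.array([float(np.mean(logit2_inv(truth.cis_profiles[g](grid))))
                          for g in range(len(genes))])
    coupled = rng.uniform(size=n_peaks) < coupling
    center = np.where(coupled, gene_rate[gidx], 0.5)

    rows = []
    for i in range(n_peaks):
        reads = {}
        ratios = []
        tot_all = 0
        for r in range(1, n_replicates + 1):
            n = int(_rnb(rng, np.array([mean_reads]), 0.1)[0])
            kb = int(_rbb(rng, np.array([n]), np.array([center[i]]), rho_peak)[0])
            reads[f"reads_rep{r}_b6"] = kb
            reads[f"reads_rep{r}_cast"] = n - kb
            if n > 0:
                ratios.append(kb / n)
            tot_all += n
        # AI is the average per-replicate read-count ratio
        ai = float(np.mean(ratios)) if ratios else np.nan
        rows.append({
            "peak": f"peak{i:05d}",
            "gene": genes[gidx[i]],
            "distance_bp": int(rng.integers(0, 20_000)),
            **reads,
            "ai": ai,
            "mean_allelic_reads": tot_all / n_replicates,
        })
    table = pd.DataFrame(rows)
    table["d"] = (table["ai"] - 0.5).abs()
    return table
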