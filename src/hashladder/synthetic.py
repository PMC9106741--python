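"""Synthetic hash-ladder experiments with known ground truth.

The generator emulates the statistical structure the method assumes:

* per-cell hash capture efficiency e_i, log-normal with mean in the
  empirically stated 0.1-1% range (default 0.5%, CV 0.5);
* concentration-dependent uptake — ladder species j in cell i is observed
  as NB(mean = e_i * expected_molecules_j, dispersion alpha);
* RNA counts sharing the cell's capture efficiency (correlation ``rho``,
  default 1 — the method's core assumption; lower it to break the
  assumption deliberately), a log-normal "biological content" multiplier,
  a condition-level global transcription multiplier, and planted per-gene
  log2 fold changes, again with NB counting noise. The expression profile
  across genes is log-normal (a few genes dominate the library, as in real
  transcriptomes);
* sample-ID hashes: one species per condition with strong counts in its own
  cells plus a Poisson ambient floor everywhere;
* read duplication: reads per cell = UMIs + Poisson(UMIs*(dup_mean - 1)),
  giving controllable hash/RNA duplication rates h_i and r_i;
* doublets (two singlets' counts summed) and debris barcodes (ambient-only).

Everything is deterministic under ``seed``; ``SimTruth`` carries what every
downstream module needs for scoring (capture efficiencies, labels, global
scales, per-gene fold changes) without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hash_io import HashCountMatrix
from .ladder import (
    AMOL,
    FMOL,
    HashSpecies,
    LadderSpec,
    ladder_from_concentrations,
    random_barcodes,
)

__all__ = [
    "Condition",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "default_ladder_48",
    "simulate_experiment",
    "simulate_hash_reads",
    "Archetype",
    "simulate_pseudotime_programs",
]


def quantile_expression_profile(n_genes: int, logsd: float = 2.0) -> np.ndarray:
    """Deterministic skewed expression profile (log-normal quantiles).

    Gene g gets the (g + 0.5)/n quantile of LogNormal(0, logsd), normalized
    to sum 1 — a fixed, reproducible library composition with the heavy top
    end real libraries show (a handful of genes absorb much of the library),
    without the seed-to-seed skew fluctuation of a random draw.
    """
    from scipy.stats import norm

    q = norm.ppf((np.arange(n_genes) + 0.5) / n_genes)
    p = np.exp(logsd * q)
    return p / p.sum()


def default_ladder_48(n_cells_per_condition: int = 100_000, seed: int = 7) -> LadderSpec:
    """48-species geometric ladder from 0.25 amol to 20 fmol."""
    concs = np.geomspace(0.25 * AMOL, 20 * FMOL, 48)
    return ladder_from_concentrations(
        list(concs),
        n_cells_per_condition=n_cells_per_condition,
        seed=seed,
        description="48-species ladder, 0.25 amol - 20 fmol",
    )


@dataclass
class Condition:
    label: str
    global_scale: float = 1.0  # condition-level transcription multiplier
    n_cells: int = 500
    treated: bool = False  # binary treatment indicator d for DE designs

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValueError("global_scale must be > 0")


@dataclass
class SimConfig:
    """Generative parameters for one synthetic experiment."""

    seed: int = 0
    n_genes: int = 200
    ladder: LadderSpec | None = None
    conditions: list[Condition] = field(
        default_factory=lambda: [Condition("control", 1.0, 500)]
    )
    capture_mean: float = 0.005  # mean nuclear capture rate (0.1-1% range)
    capture_cv: float = 0.5
    rho: float = 1.0  # hash-RNA capture correlation
    nb_dispersion: float = 0.2
    rna_depth_mean: float = 5000.0
    content_cv: float = 0.0  # biological per-cell RNA content CV (log-normal)
    expr_logsd: float = 1.5  # spread of the log-normal expression profile
    expr_profile: np.ndarray | None = None  # explicit profile overrides the draw
    de_log2fc: np.ndarray | None = None  # per-gene log2 FC applied when treated
    de_log2fc_sd: float = 0.0  # draw a centered symmetric log2 FC scatter instead
    doublet_rate: float = 0.0
    n_debris: int = 0
    debris_rna_mean: float = 20.0
    ambient_id_rate: float = 0.5  # ambient ID-hash counts per species
    ambient_ladder_rate: float = 0.05  # ambient ladder counts per species
    id_signal_mean: float = 300.0  # mean own-label ID-hash UMIs for a typical cell
    duplication_mean: float = 1.5  # mean reads per UMI

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must be in [0, 1]")
        if self.capture_mean <= 0 or self.capture_cv < 0:
            raise ValueError("invalid capture efficiency parameters")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with emitted cells."""

    cells: pd.DataFrame  # capture, label, global_scale, treated, is_doublet, is_debris
    gene_log2fc: np.ndarray


@dataclass
class SimResult:
    ladder: LadderSpec  # includes the sample-ID species
    hash_counts: HashCountMatrix  # ladder species only
    id_counts: HashCountMatrix  # sample-ID species only
    gene_counts: sp.csr_matrix  # cells x genes
    metadata: pd.DataFrame  # per-cell observables (UMI/read tallies)
    truth: SimTruth


def _lognormal(rng, mean: float, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _nb(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with NB2 dispersion alpha (Poisson when 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / alpha, alpha * mean)
    return rng.poisson(lam)


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate a full experiment: ladder hashes, ID hashes, genes, truth."""
    rng = np.random.default_rng(config.seed)
    ladder = config.ladder if config.ladder is not None else default_ladder_48()
    from .ladder import expected_molecules_per_cell

    expected = expected_molecules_per_cell(ladder)
    ladder_ids = [s.species_id for s in ladder.ladder_species]
    exp_vec = np.array([expected[s] for s in ladder_ids])

    # projected feasibility: warn when every species lands below 1 UMI
    if (config.capture_mean * exp_vec).max() < 1:
        import warnings

        warnings.warn(
            "config projects < 1 expected hash UMI for every ladder species; "
            f"max projected mean = {(config.capture_mean * exp_vec).max():.3g}"
        )

    n_conditions = len(config.conditions)
    id_barcodes = random_barcodes(
        n_conditions, seed=rng.integers(2**31), min_distance=5
    )
    id_species = [
        HashSpecies(f"ID_{c.label}", id_barcodes[k], 0.4 * FMOL * 1e3, role="sample_id")
        for k, c in enumerate(config.conditions)
    ]
    full_ladder = ladder.with_id_species(id_species)
    id_ids = [s.species_id for s in id_species]

    # gene expression profile (shared across conditions), normalized to sum 1
    if config.expr_profile is not None:
        p_g = np.asarray(config.expr_profile, dtype=float)
        if p_g.shape != (config.n_genes,) or np.any(p_g <= 0):
            raise ValueError("expr_profile must be n_genes positive values")
        p_g = p_g / p_g.sum()
    else:
        p_g = _lognormal(
            rng, 1.0, np.sqrt(np.expm1(config.expr_logsd**2)), config.n_genes
        )
        p_g = rng.permutation(p_g)
        p_g /= p_g.sum()
    if config.de_log2fc is not None:
        lfc = np.asarray(config.de_log2fc, dtype=float)
    elif config.de_log2fc_sd > 0:
        # symmetric per-gene scatter, centered so the count-weighted aggregate
        # multiplier is exactly 1: the global_scale alone sets the total shift
        lfc = rng.normal(0, config.de_log2fc_sd, config.n_genes)
        lfc -= np.log2(np.sum(p_g * 2.0**lfc))
    else:
        lfc = np.zeros(config.n_genes)
    if lfc.shape != (config.n_genes,):
        raise ValueError("de_log2fc must have length n_genes")

    n_singlets = sum(c.n_cells for c in config.conditions)
    labels = np.concatenate(
        [[c.label] * c.n_cells for c in config.conditions]
    )
    scales = np.concatenate(
        [[c.global_scale] * c.n_cells for c in config.conditions]
    ).astype(float)
    treated = np.concatenate(
        [[c.treated] * c.n_cells for c in config.conditions]
    ).astype(bool)

    # correlated log-normal capture efficiencies for hash and RNA
    sigma2 = np.log1p(config.capture_cv**2)
    sigma = np.sqrt(sigma2)
    w_hash = rng.standard_normal(n_singlets)
    w_ind = rng.standard_normal(n_singlets)
    e_hash = np.exp(np.log(config.capture_mean) - sigma2 / 2 + sigma * w_hash)
    w_rna = config.rho * w_hash + np.sqrt(max(0.0, 1 - config.rho**2)) * w_ind
    u_rna = np.exp(sigma * w_rna - sigma2 / 2)  # relative RNA efficiency, mean 1
    content = _lognormal(rng, 1.0, config.content_cv, n_singlets)

    # ladder hash counts: NB(e_i * expected_j)
    hash_mean = e_hash[:, None] * exp_vec[None, :]
    hash_counts = _nb(rng, hash_mean, config.nb_dispersion)
    hash_counts += rng.poisson(config.ambient_ladder_rate, size=hash_counts.shape)

    # sample-ID hash counts: own-label signal + ambient floor
    id_counts = rng.poisson(config.ambient_id_rate, size=(n_singlets, n_conditions))
    label_to_col = {c.label: k for k, c in enumerate(config.conditions)}
    own_col = np.array([label_to_col[l] for l in labels])
    signal_mean = config.id_signal_mean * e_hash / config.capture_mean
    id_signal = _nb(rng, signal_mean, config.nb_dispersion)
    id_counts[np.arange(n_singlets), own_col] += id_signal

    # gene counts: NB(u_i * content_i * scale_c * depth * p_g * 2^(lfc*d))
    gene_mult = np.where(treated[:, None], 2.0 ** lfc[None, :], 1.0)
    gene_mean = (
        (u_rna * content * scales * config.rna_depth_mean)[:, None]
        * p_g[None, :]
        * gene_mult
    )
    gene_counts = _nb(rng, gene_mean, config.nb_dispersion)

    is_doublet = np.zeros(n_singlets, dtype=bool)
    is_debris = np.zeros(n_singlets, dtype=bool)

    # doublets: sum two singlets from different conditions (the detectable,
    # cross-sample collision; same-label collisions look like singlets)
    n_doublets = int(round(config.doublet_rate * n_singlets))
    if n_doublets:
        if n_conditions < 2:
            raise ValueError("doublets require >= 2 conditions")
        pair_a = rng.integers(0, n_singlets, n_doublets)
        pair_b = rng.integers(0, n_singlets, n_doublets)
        same = labels[pair_a] == labels[pair_b]
        while same.any():
            pair_b[same] = rng.integers(0, n_singlets, int(same.sum()))
            same = labels[pair_a] == labels[pair_b]
        hash_counts = np.vstack([hash_counts, hash_counts[pair_a] + hash_counts[pair_b]])
        id_counts = np.vstack([id_counts, id_counts[pair_a] + id_counts[pair_b]])
        gene_counts = np.vstack([gene_counts, gene_counts[pair_a] + gene_counts[pair_b]])
        labels = np.concatenate([labels, ["doublet"] * n_doublets])
        scales = np.concatenate([scales, (scales[pair_a] + scales[pair_b]) / 2])
        treated = np.concatenate([treated, treated[pair_a] | treated[pair_b]])
        e_hash = np.concatenate([e_hash, e_hash[pair_a] + e_hash[pair_b]])
        is_doublet = np.concatenate([is_doublet, np.ones(n_doublets, dtype=bool)])
        is_debris = np.concatenate([is_debris, np.zeros(n_doublets, dtype=bool)])

    # debris barcodes: ambient-only
    if config.n_debris:
        nd = config.n_debris
        hash_counts = np.vstack(
            [hash_counts, rng.poisson(config.ambient_ladder_rate, (nd, len(ladder_ids)))]
        )
        id_counts = np.vstack(
            [id_counts, rng.poisson(config.ambient_id_rate, (nd, n_conditions))]
        )
        debris_genes = rng.poisson(
            config.debris_rna_mean * p_g[None, :], (nd, config.n_genes)
        )
        gene_counts = np.vstack([gene_counts, debris_genes])
        labels = np.concatenate([labels, ["debris"] * nd])
        scales = np.concatenate([scales, np.ones(nd)])
        treated = np.concatenate([treated, np.zeros(nd, dtype=bool)])
        e_hash = np.concatenate([e_hash, np.zeros(nd)])
        is_doublet = np.concatenate([is_doublet, np.zeros(nd, dtype=bool)])
        is_debris = np.concatenate([is_debris, np.ones(nd, dtype=bool)])

    n_total = len(labels)
    barcodes = [f"CELL{i:06d}" for i in range(n_total)]

    hash_umis = hash_counts.sum(axis=1)
    rna_umis = gene_counts.sum(axis=1)
    extra = config.duplication_mean - 1.0
    hash_reads = hash_umis + rng.poisson(np.maximum(hash_umis * extra, 0))
    rna_reads = rna_umis + rng.poisson(np.maximum(rna_umis * extra, 0))

    metadata = pd.DataFrame(
        {
            "cell_barcode": barcodes,
            "rna_umis": rna_umis,
            "rna_reads": rna_reads,
            "hash_umis": hash_umis,
            "hash_reads": hash_reads,
        }
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "cell_barcode": barcodes,
                "capture": e_hash,
                "label": labels,
                "global_scale": scales,
                "treated": treated,
                "is_doublet": is_doublet,
                "is_debris": is_debris,
            }
        ),
        gene_log2fc=lfc,
    )
    return SimResult(
        ladder=full_ladder,
        hash_counts=HashCountMatrix(barcodes, ladder_ids, sp.csr_matrix(hash_counts)),
        id_counts=HashCountMatrix(barcodes, id_ids, sp.csr_matrix(id_counts)),
        gene_counts=sp.csr_matrix(gene_counts),
        metadata=metadata,
        truth=truth,
    )


def simulate_hash_reads(
    result: SimResult,
    seed: int = 0,
    umi_len: int = 8,
    duplication_mean: float | None = None,
    error_rate: float = 0.0,
):
    """Expand a simulated hash count matrix into read-level records.

    Yields (cell_barcode, umi, read2) tuples suitable for
    :func:`hashladder.hash_io.count_hashes`; read2 is the species barcode,
    a spacer base, then poly(A). ``error_rate`` injects per-base
    substitutions into the barcode portion. Intended for small configs
    (read-level data is bulky).
    """
    rng = np.random.default_rng(seed)
    dup = duplication_mean if duplication_mean is not None else 1.5
    barcode_of = {s.species_id: s.barcode for s in result.ladder.species}
    bases = np.array(list("ACGT"))
    for matrix in (result.hash_counts, result.id_counts):
        for cell, species_id, count in matrix.nonzeros():
            bc = barcode_of[species_id]
            for _ in range(count):
                umi = "".join(rng.choice(bases, umi_len))
                n_reads = 1 + rng.poisson(max(dup - 1, 0))
                for _ in range(n_reads):
                    read_bc = list(bc)
                    if error_rate > 0:
                        for pos in range(len(read_bc)):
                            if rng.random() < error_rate:
                                read_bc[pos] = str(rng.choice(bases))
                    yield cell, umi, "".join(read_bc) + "C" + "A" * 6


@dataclass
class Archetype:
    """A kinetic shape for pseudotime-dependent expression.

    kind: 'sigmoid' (monotone up/down with a midpoint), 'transient'
    (Gaussian bump at ``midpoint``), or 'flat'. ``amplitude`` is the
    high/low mean ratio; ``steepness`` the sigmoid scale in pseudotime
    units.
    """

    kind: str = "sigmoid"
    midpoint: float = 0.5
    direction: str = "up"
    amplitude: float = 8.0
    steepness: float = 0.08
    width: float = 0.1  # transient bump width

    def shape(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            return np.ones_like(t)
        if self.kind == "sigmoid":
            s = 1.0 / (1.0 + np.exp(-(t - self.midpoint) / self.steepness))
            if self.direction == "down":
                s = 1.0 - s
            return 1.0 + (self.amplitude - 1.0) * s
        if self.kind == "transient":
            return 1.0 + (self.amplitude - 1.0) * np.exp(
                -((t - self.midpoint) ** 2) / (2 * self.width**2)
            )
        raise ValueError(f"unknown archetype kind {self.kind!r}")


def true_onset(arch: Archetype, grid_size: int = 2001) -> float:
    """Analytic onset of an archetype: first crossing of its trajectory mean.

    Computed on a fine grid over [0, 1] exactly as the estimator defines
    onset (centered curve, first upward zero-crossing, interpolated).
    """
    grid = np.linspace(0, 1, grid_size)
    z = arch.shape(grid)
    z = z - z.mean()
    idx = np.nonzero((z[:-1] < 0) & (z[1:] >= 0))[0]
    if idx.size == 0:
        raise ValueError("archetype never crosses its mean upward")
    i = idx[0] + 1
    frac = -z[i - 1] / (z[i] - z[i - 1])
    return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))


def sigmoid_with_onset(
    onset: float,
    amplitude: float = 8.0,
    steepness: float = 0.08,
) -> Archetype:
    """Upregulated sigmoid whose true onset (mean-crossing) equals ``onset``.

    The logistic midpoint is solved so the curve crosses its trajectory-wide
    mean exactly at the requested pseudotime — the quantity the onset
    estimator targets. For a central onset the midpoint nearly coincides;
    off-center onsets shift the midpoint slightly because the mean level
    itself depends on where the switch sits.
    """
    from scipy.optimize import brentq

    def f(mid):
        return (
            true_onset(Archetype("sigmoid", mid, amplitude=amplitude, steepness=steepness))
            - onset
        )

    mid = brentq(f, 0.02, 0.98)
    return Archetype("sigmoid", mid, amplitude=amplitude, steepness=steepness)


def simulate_pseudotime_programs(
    archetypes: list[Archetype],
    n_cells: int = 300,
    seed: int = 0,
    base_mean: float = 20.0,
    nb_dispersion: float = 0.1,
):
    """Gene counts with pseudotime-dependent means plus ground truth.

    Pseudotime ~ Uniform[0, 1] per cell; gene g follows archetype g's shape
    scaled to ``base_mean`` at the low state. Returns (counts cells x genes,
    pseudotime, truth DataFrame with the archetype parameters).
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n_cells)
    counts = np.empty((n_cells, len(archetypes)), dtype=np.int64)
    rows = []
    for g, arch in enumerate(archetypes):
        mean = base_mean * arch.shape(t)
        counts[:, g] = _nb(rng, mean, nb_dispersion)
        rows.append(
            {
                "gene": f"g{g}",
                "kind": arch.kind,
                "midpoint": arch.midpoint,
                "direction": arch.direction,
            }
        )
    return counts, t, pd.DataFrame(rows)
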