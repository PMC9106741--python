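"""Differential expression with NB GLMs and size-factor offsets.

Per gene, a negative-binomial GLM with log link is fit with the natural log
of the cell-specific size factor as offset:

    log E[y_g] = X beta + ln(f)

Designs cover a 3-df natural-spline of pseudotime (time-course trajectories)
or a binary treatment indicator d (e.g. dexamethasone), plus optional
categorical covariates (plate, drug, dose) dummy-coded against a reference
level. Significance comes from a likelihood-ratio test of the full against
a reduced (nested) design, chi-square with df = rank difference, BH
adjusted across genes.

The choice of size factors is the whole point: a global shift in
transcription is absorbed by conventional (total-UMI) factors, so DE calls
split symmetrically up/down even when transcription is globally repressed;
hash-ladder factors preserve the shift, and the calls skew down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import NaturalSpline, fit_nb_glm

__all__ = [
    "DeModelSpec",
    "DEModel",
    "DEResults",
    "build_design",
    "fit_gene_glm",
    "lrt",
    "bh_adjust",
    "dex_responsive_genes",
    "classify_unresponsive_gene",
    "percent_expressing_bootstrap",
]

LOG2 = float(np.log(2.0))


@dataclass
class DeModelSpec:
    """Model terms for the per-gene GLM.

    ``pseudotime`` names a metadata column smoothed with a natural spline
    (``spline_df`` degrees of freedom); ``treatment`` a binary 0/1 column;
    ``covariates`` categorical columns dummy-coded against their first
    level. ``reduced_terms`` lists the term names kept in the reduced model
    for the LRT (default: covariates only, so the LRT targets the
    pseudotime/treatment effect).
    """

    pseudotime: str | None = None
    treatment: str | None = None
    covariates: list[str] = field(default_factory=list)
    spline_df: int = 3
    reduced_terms: list[str] | None = None


def build_design(
    metadata: pd.DataFrame, spec: DeModelSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix, column names, and a full-vs-reduced column mask.

    Returns (X, names, reduced_mask) where ``reduced_mask`` selects the
    columns of the reduced design (always including the intercept).
    """
    n = len(metadata)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    terms: list[str] = ["intercept"]

    if spec.pseudotime is not None:
        t = metadata[spec.pseudotime].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("pseudotime must be finite for all cells")
        basis = NaturalSpline(t, df=spec.spline_df).design(t)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"ns({spec.pseudotime})[{j}]")
            terms.append(spec.pseudotime)
    if spec.treatment is not None:
        d = metadata[spec.treatment].to_numpy(dtype=float)
        u = np.unique(d)
        if u.size < 2:
            raise ValueError(f"treatment column {spec.treatment!r} is constant")
        if not set(u) <= {0.0, 1.0}:
            raise ValueError("treatment must be binary 0/1")
        cols.append(d)
        names.append(spec.treatment)
        terms.append(spec.treatment)
    for cov in spec.covariates:
        v = metadata[cov].astype("category")
        levels = list(v.cat.categories)
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        for lev in levels[1:]:
            cols.append((v == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
            terms.append(cov)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    reduced_keep = set(["intercept"] + (spec.reduced_terms or spec.covariates))
    reduced_mask = np.array([t in reduced_keep for t in terms])
    return X, names, reduced_mask


def fit_gene_glm(y, design, offset=None, alpha: float | None = None):
    """NB GLM for one gene; thin wrapper kept for a stable surface."""
    return fit_nb_glm(np.asarray(y, dtype=float), design, offset=offset, alpha=alpha)


def lrt(full, reduced, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: 2*(ll_full - ll_reduced)."""
    if df < 1:
        raise ValueError("rank difference must be >= 1")
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


class DEModel:
    """Per-gene NB-GLM differential expression over a count matrix.

    Parameters
    ----------
    counts : array or sparse, cells x genes
    metadata : DataFrame aligned with rows of ``counts``
    spec : DeModelSpec
    size_factors : per-cell factors whose natural log becomes the offset
    gene_names : optional labels for the columns
    """

    def __init__(self, counts, metadata, spec, size_factors, gene_names=None):
        self.counts = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
        self.metadata = metadata.reset_index(drop=True)
        self.spec = spec
        f = np.asarray(size_factors, dtype=float)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("size factors must be finite and > 0")
        self.offset = np.log(f)
        n_genes = self.counts.shape[1]
        self.gene_names = (
            list(gene_names) if gene_names is not None else [f"g{i}" for i in range(n_genes)]
        )
        self.X, self.colnames, self.reduced_mask = build_design(self.metadata, spec)

    def _gene(self, j) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts[:, j].todense()).ravel()
        return self.counts[:, j].astype(float)

    def fit(self, min_cells_expressed: int = 0) -> "DEResults":
        """Fit every gene; LRT of full vs. reduced design.

        Genes expressed in fewer than ``min_cells_expressed`` cells, or with
        all-zero counts, or failing to converge are marked failed and
        excluded from the BH adjustment.
        """
        Xr = self.X[:, self.reduced_mask]
        df_diff = int(
            np.linalg.matrix_rank(self.X) - np.linalg.matrix_rank(Xr)
        )
        rows = []
        for j, g in enumerate(self.gene_names):
            y = self._gene(j)
            n_expr = int(np.sum(y > 0))
            if n_expr == 0 or n_expr < min_cells_expressed:
                rows.append(
                    dict(gene=g, n_cells_expressed=n_expr, status="failed",
                         lrt_stat=np.nan, p_value=np.nan)
                )
                continue
            full = fit_nb_glm(y, self.X, offset=self.offset)
            reduced = fit_nb_glm(y, Xr, offset=self.offset, alpha=full.alpha)
            if not (full.converged and reduced.converged):
                rows.append(
                    dict(gene=g, n_cells_expressed=n_expr, status="failed",
                         lrt_stat=np.nan, p_value=np.nan)
                )
                continue
            stat, p = lrt(full, reduced, df_diff)
            row = dict(
                gene=g,
                n_cells_expressed=n_expr,
                status="ok",
                lrt_stat=stat,
                p_value=p,
                dispersion=full.alpha,
            )
            for name, b in zip(self.colnames, full.beta):
                row[f"coef_{name}"] = b
            if self.spec.treatment is not None:
                # natural-log coefficient -> log2 fold change
                idx = self.colnames.index(self.spec.treatment)
                row["log2fc"] = full.beta[idx] / LOG2
            rows.append(row)
        table = pd.DataFrame(rows)
        ok = table.status == "ok"
        table["q_value"] = np.nan
        if ok.any():
            table.loc[ok, "q_value"] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
        return DEResults(self, table, df_diff)


class DEResults:
    """Per-gene DE table with LRT p/q values and coefficients."""

    def __init__(self, model, table: pd.DataFrame, lrt_df: int):
        self.model = model
        self.table = table
        self.lrt_df = lrt_df

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t.status == "ok") & (t.q_value < fdr)].reset_index(drop=True)

    def summary(self, fdr: float = 0.05) -> str:
        t = self.table
        sig = self.significant(fdr)
        lines = [
            "NB-GLM differential expression",
            "=" * 40,
            f"genes tested:      {int((t.status == 'ok').sum())} "
            f"(of {len(t)}; {int((t.status == 'failed').sum())} failed)",
            f"LRT df:            {self.lrt_df}",
            f"significant (q<{fdr:g}): {len(sig)}",
        ]
        if "log2fc" in sig.columns and len(sig):
            down = int((sig.log2fc < 0).sum())
            lines.append(
                f"  down / up:       {down} / {len(sig) - down}"
            )
        return "\n".join(lines)


def dex_responsive_genes(
    counts,
    metadata: pd.DataFrame,
    size_factors,
    treatment: str = "dex",
    covariates: list[str] | None = None,
    fdr: float = 0.05,
    gene_names=None,
    min_cells_expressed: int = 0,
) -> pd.DataFrame:
    """Genes with a significant binary-treatment term (q < fdr).

    Intended for the treated-vs-vehicle comparison among cells that received
    no other perturbation; returns the DE table restricted to significant
    genes with their log2 fold changes.
    """
    d = metadata[treatment].to_numpy(dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("treatment column is constant; no treated/control contrast")
    spec = DeModelSpec(treatment=treatment, covariates=covariates or [])
    res = DEModel(counts, metadata, spec, size_factors, gene_names).fit(
        min_cells_expressed=min_cells_expressed
    )
    return res.significant(fdr)


def classify_unresponsive_gene(
    dex_significant_alone: bool,
    responds_under_hdaci: bool,
    hdaci_alone_lfc: float,
    hdaci_alone_significant: bool,
    dex_alone_lfc: float,
) -> str:
    """Classify why a normally DEX-responsive gene fails to respond under HDACi.

    * responsive — still responds to DEX despite HDAC inhibition;
    * saturated — HDACi alone already moves it in the same direction as DEX;
    * dominated — HDACi alone moves it in the opposite direction;
    * attenuated — HDACi alone leaves it unchanged, yet it cannot respond.
    """
    if not dex_significant_alone:
        raise ValueError("classification applies to DEX-responsive genes only")
    if responds_under_hdaci:
        return "responsive"
    if hdaci_alone_significant:
        s = np.sign(hdaci_alone_lfc) * np.sign(dex_alone_lfc)
        if s > 0:
            return "saturated"
        if s < 0:
            return "dominated"
        # zero lfc with nominal significance: no direction to compare
        return "attenuated"
    return "attenuated"


def percent_expressing_bootstrap(
    values,
    threshold: float = 1.0,
    n_boot: int = 100,
    ci: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Percent of cells with normalized expression above ``threshold``.

    Point estimate plus a percentile bootstrap CI (resampling cells with
    replacement, ``n_boot`` resamples, seeded).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("group is empty")
    rng = np.random.default_rng(seed)
    point = 100.0 * np.mean(v > threshold)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boots = 100.0 * np.mean(v[idx] > threshold, axis=1)
    lo, hi = np.percentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(point), (float(lo), float(hi))
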