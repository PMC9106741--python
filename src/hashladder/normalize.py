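"""Cell-specific size factors and matrix normalization.

Two size-factor families, both rescaled to unit geometric mean so that a
factor of 1 means "typical cell":

* conventional:  f_i proportional to x_i, the cell's total RNA UMIs —
  assumes all cells have the same total RNA content, so any global shift in
  transcription is invisible after normalization;
* hash ladder:   f'_i proportional to log(z_i / h_i) * m_i / (-b_i) * r_i,
  built from the ladder calibration (z_i total ladder UMIs, h_i hash
  duplication rate, m_i slope, b_i intercept, r_i RNA duplication rate) —
  an external standard, independent of the transcriptome, so global shifts
  survive normalization.

Logs are natural throughout, consistent with the log-link calibration GLM.
Duplication rates are reads/UMIs (>= 1); a ``rate_def="one_minus"``
switch provides the alternative 1 - UMIs/reads definition for sensitivity
analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "conventional_size_factors",
    "hash_size_factors",
    "build_cell_normalization",
    "normalize_matrix",
    "cv_per_gene",
    "aggregate_totals_by_group",
]


def _geometric_mean(v: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(v))))


def conventional_size_factors(x) -> np.ndarray:
    """f_i = x_i / geometric_mean(x); unit geometric mean by construction."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("all RNA totals must be > 0 (pre-filter empty cells)")
    return x / _geometric_mean(x)


def duplication_rate(reads, umis, rate_def: str = "ratio") -> np.ndarray:
    """reads/UMIs (default, >= 1) or 1 - UMIs/reads."""
    reads = np.asarray(reads, dtype=float)
    umis = np.asarray(umis, dtype=float)
    if np.any(umis <= 0):
        raise ValueError("UMI totals must be > 0")
    if np.any(reads < umis):
        raise ValueError("read totals cannot be below UMI totals")
    if rate_def == "ratio":
        return reads / umis
    if rate_def == "one_minus":
        return 1.0 - umis / reads
    raise ValueError(f"unknown rate_def {rate_def!r}")


def hash_size_factors(norms: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Hash-ladder size factors from calibration parameters.

    ``norms`` needs columns z (total ladder UMIs), h (hash duplication
    rate), m (slope), b (intercept), r (RNA duplication rate). Returns
    (f_prime, included): the raw quantity g_i = ln(z_i/h_i) * m_i/(-b_i) * r_i
    rescaled to unit geometric mean over included cells; cells violating the
    preconditions (b >= 0, m <= 0, or z/h <= 1, all symptoms of a broken
    calibration) are excluded with f' = NaN rather than clamped.
    """
    z = norms["z"].to_numpy(dtype=float)
    h = norms["h"].to_numpy(dtype=float)
    m = norms["m"].to_numpy(dtype=float)
    b = norms["b"].to_numpy(dtype=float)
    r = norms["r"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = (b < 0) & (m > 0) & (z / h > 1) & np.isfinite(m) & np.isfinite(b)
        g = np.where(valid, np.log(z / h) * m / (-b) * r, np.nan)
    if not valid.any():
        raise ValueError("no cells satisfy the hash size-factor preconditions")
    f = np.full(z.shape, np.nan)
    f[valid] = g[valid] / _geometric_mean(g[valid])
    return f, valid


def build_cell_normalization(
    cell_barcodes,
    rna_umis,
    rna_reads,
    hash_umis,
    hash_reads,
    slope,
    intercept,
    rate_def: str = "ratio",
) -> pd.DataFrame:
    """Assemble the per-cell normalization table and both factor sets.

    Columns: cell_barcode, x, z, h, r, m, b, f_conventional, f_hash,
    included (hash-factor validity).
    """
    df = pd.DataFrame(
        {
            "cell_barcode": list(cell_barcodes),
            "x": np.asarray(rna_umis, dtype=float),
            "z": np.asarray(hash_umis, dtype=float),
            "h": duplication_rate(hash_reads, hash_umis, rate_def),
            "r": duplication_rate(rna_reads, rna_umis, rate_def),
            "m": np.asarray(slope, dtype=float),
            "b": np.asarray(intercept, dtype=float),
        }
    )
    df["f_conventional"] = conventional_size_factors(df["x"].to_numpy())
    f_hash, included = hash_size_factors(df)
    df["f_hash"] = f_hash
    df["included"] = included
    return df


def normalize_matrix(counts, factors, log1p: bool = False):
    """Divide each cell's counts by its size factor; optional ln(1 + .).

    ``counts`` is cell x gene (dense or sparse); returns the same layout.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factors must be finite and > 0")
    if sp.issparse(counts):
        if counts.shape[0] != factors.size:
            raise ValueError("factors must align with matrix rows (cells)")
        out = sp.diags(1.0 / factors) @ counts.tocsr()
        if log1p:
            out = out.copy()
            out.data = np.log1p(out.data)
        return out
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != factors.size:
        raise ValueError("factors must align with matrix rows (cells)")
    out = counts / factors[:, None]
    return np.log1p(out) if log1p else out


def cv_per_gene(normalized) -> pd.DataFrame:
    """Per-gene mean and coefficient of variation over cells.

    CV = sd/mean with the n-1 sd. Genes with zero mean are excluded and
    reported via the returned frame's index gap (column ``gene`` is the
    original column position).
    """
    if sp.issparse(normalized):
        normalized = np.asarray(normalized.todense())
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[0] < 2:
        raise ValueError("need >= 2 cells")
    mean = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=1)
    keep = mean > 0
    return pd.DataFrame(
        {
            "gene": np.nonzero(keep)[0],
            "mean": mean[keep],
            "cv": sd[keep] / mean[keep],
        }
    )


def aggregate_totals_by_group(rna_umis, factors, groups) -> pd.Series:
    """Per-group mean of normalized total RNA (x_i / f_i).

    Detects shifts in global transcriptional output between condition
    groups — only meaningful with hash-ladder factors, since conventional
    factors make every cell's normalized total identical by construction.
    """
    x = np.asarray(rna_umis, dtype=float)
    f = np.asarray(factors, dtype=float)
    groups = pd.Series(list(groups))
    if groups.isna().any():
        raise ValueError("every cell must carry a group label")
    norm_tot = pd.Series(x / f)
    out = norm_tot.groupby(groups.values).mean()
    empty = set(groups.unique()) - set(out.index)
    if empty:
        warnings.warn(f"empty groups omitted: {sorted(empty)}")
    return out
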