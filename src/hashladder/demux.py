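"""Sample assignment from sample-ID hash oligos.

Each experimental condition labels its nuclei with one dedicated hash
species; a nucleus is assigned to the condition whose hash dominates its
ID-hash counts. Three safeguards:

* background filter — nuclei whose total ID-hash UMIs do not exceed the
  ambient background (estimated from debris barcodes) are dropped
  (Poisson upper tail, BH-corrected, FDR < 0.01 by default);
* enrichment ratio — top/second species count ratio must reach a cutoff
  (default 10) for a confident single-label call;
* doublet flag — a sub-cutoff ratio with a second species that itself
  stands above background marks a collision of two labeled nuclei.

Ladder-role species never participate; they are the calibration standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hash_io import HashCountMatrix

__all__ = [
    "BackgroundProfile",
    "estimate_background",
    "test_against_background",
    "assign_samples",
]

ASSIGNED = "assigned"
UNLABELED = "unlabeled"
DOUBLET = "doublet"
BACKGROUND = "background"


@dataclass
class BackgroundProfile:
    """Ambient ID-hash profile estimated from debris barcodes."""

    per_species_mean: pd.Series  # species_id -> mean ambient count
    mean_total: float
    n_debris: int


def estimate_background(
    id_counts: HashCountMatrix,
    rna_totals,
    debris_cutoff: float,
    min_debris: int = 20,
) -> BackgroundProfile:
    """Average ID-hash counts over barcodes that look like debris.

    Debris = barcodes whose total RNA UMIs fall below ``debris_cutoff``
    (e.g. below the knee threshold). Needs >= ``min_debris`` such barcodes.
    """
    rna_totals = np.asarray(rna_totals, dtype=float)
    if rna_totals.size != len(id_counts.cells):
        raise ValueError("rna_totals must align with id_counts cells")
    debris = rna_totals < debris_cutoff
    n = int(debris.sum())
    if n < min_debris:
        raise ValueError(
            f"only {n} barcodes below debris_cutoff={debris_cutoff}; "
            "raise the cutoff or supply more barcodes"
        )
    dense = id_counts.dense()[debris]
    per_species = pd.Series(dense.mean(axis=0), index=id_counts.species)
    return BackgroundProfile(per_species, float(per_species.sum()), n)


def test_against_background(
    cell_total_id_umis,
    background_mean_total: float,
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Poisson upper-tail test of each cell's ID-hash total vs. background.

    p = P(X >= observed | mean = background_mean_total); BH adjustment
    across cells; keep iff q < fdr_cutoff.
    """
    if background_mean_total <= 0:
        raise ValueError("background mean must be > 0")
    obs = np.asarray(cell_total_id_umis, dtype=float)
    p = stats.poisson.sf(obs - 1, mu=background_mean_total)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"p_value": p, "q_value": q, "keep": q < fdr_cutoff})


def assign_samples(
    id_counts: HashCountMatrix,
    background: BackgroundProfile,
    ratio_cutoff: float = 10.0,
    fdr_cutoff: float = 0.01,
    doublet_second_p: float = 0.01,
) -> pd.DataFrame:
    """Per-cell sample calls from ID-hash counts.

    Cells failing the background test are ``background``; passing cells
    with top/second ratio >= ``ratio_cutoff`` (ratio = inf when the second
    count is 0) are ``assigned`` to the top species; sub-cutoff cells whose
    second species individually exceeds its ambient level (Poisson tail
    p < ``doublet_second_p``) are ``doublet``; the rest are ``unlabeled``.
    """
    if len(id_counts.species) < 1:
        raise ValueError("need at least one sample-ID species")
    dense = id_counts.dense().astype(float)
    totals = dense.sum(axis=1)
    bg = test_against_background(totals, background.mean_total, fdr_cutoff)

    order = np.argsort(dense, axis=1)
    top_idx = order[:, -1]
    second_idx = order[:, -2] if dense.shape[1] > 1 else top_idx
    top = dense[np.arange(len(dense)), top_idx]
    second = (
        dense[np.arange(len(dense)), second_idx]
        if dense.shape[1] > 1
        else np.zeros(len(dense))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, top / np.maximum(second, 1e-300), np.inf)

    species = np.asarray(id_counts.species)
    second_bg_mean = background.per_species_mean.reindex(species[second_idx]).to_numpy()
    second_p = stats.poisson.sf(second - 1, mu=np.maximum(second_bg_mean, 1e-12))

    calls = np.full(len(dense), UNLABELED, dtype=object)
    calls[~bg["keep"].to_numpy()] = BACKGROUND
    passing = bg["keep"].to_numpy()
    assigned = passing & (ratio >= ratio_cutoff) & (top > 0)
    calls[assigned] = ASSIGNED
    doublet = passing & ~assigned & (second_p < doublet_second_p) & (second > 0)
    calls[doublet] = DOUBLET

    return pd.DataFrame(
        {
            "cell_barcode": id_counts.cells,
            "call": calls,
            "sample": np.where(calls == ASSIGNED, species[top_idx], ""),
            "top_species": species[top_idx],
            "second_species": np.where(
                dense.shape[1] > 1, species[second_idx], ""
            ),
            "enrichment_ratio": ratio,
            "p_value": bg["p_value"].to_numpy(),
            "q_value": bg["q_value"].to_numpy(),
        }
    )
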