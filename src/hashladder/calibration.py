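"""Per-cell hash-ladder calibration curves.

For each cell the observed UMI count of ladder species j is regressed on the
expected number of molecules per nucleus with a negative-binomial GLM and
log link:

    log E[obs_j] = b_i + m_i * log(expected_j)

i.e. a power law E[obs] = e^{b_i} * expected^{m_i}. For a well-behaved cell
the slope m_i is near 1 (uptake proportional to concentration) and the
intercept b_i is the log capture efficiency, hence negative. A
deviance-based pseudo-R-squared of the fit serves as a per-cell QC score:
cells whose ladder is poorly described by their own calibration line, or
with too few ladder UMIs or detected species, are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import GLMFit, fit_nb_glm, nb_deviance
from .hash_io import HashCountMatrix
from .ladder import LadderSpec, expected_molecules_per_cell

__all__ = [
    "CalibrationFit",
    "QcConfig",
    "CalibrationModel",
    "CalibrationResults",
    "fit_cell_calibration",
    "pseudo_r2",
    "qc_filter",
]


@dataclass
class QcConfig:
    """Cell-level QC thresholds on the calibration fit.

    Cells pass when pseudo_r2 >= r2_min, total ladder UMIs >= min_hash_umis,
    detected ladder species >= min_species, and the fit converged. The UMI
    boundary is keep-if->=100 (the discard rule is "less than 100").
    """

    r2_min: float = 0.7
    min_hash_umis: int = 100
    min_species: int = 10

    def __post_init__(self) -> None:
        if self.r2_min < 0 or self.min_hash_umis < 0 or self.min_species < 0:
            raise ValueError("QC thresholds must be >= 0")


@dataclass
class CalibrationFit:
    """Calibration line parameters for one cell."""

    cell_barcode: str
    slope: float
    intercept: float
    dispersion: float
    pseudo_r2: float
    total_hash_umis: int
    n_species_detected: int
    converged: bool
    error: str | None = None  # set when the fit could not be attempted


def pseudo_r2(observed, expected, fit: GLMFit) -> float:
    """Deviance-based pseudo-R2: 1 - D_model / D_null.

    Both deviances are evaluated at the model's fitted dispersion; the null
    model is intercept-only (refit at the same dispersion). Equals 1 when
    the fitted means match the observations exactly and 0 when the model
    explains nothing beyond the mean. Defined as 0 when D_null = 0 (all
    counts identical).
    """
    y = np.asarray(observed, dtype=float)
    d_model = nb_deviance(y, fit.mu, fit.alpha)
    null = fit_nb_glm(y, np.ones((y.size, 1)), alpha=fit.alpha)
    d_null = nb_deviance(y, null.mu, fit.alpha)
    if d_null <= 0:
        return 0.0
    return 1.0 - d_model / d_null


def fit_cell_calibration(
    observed,
    expected,
    cell_barcode: str = "",
    alpha: float | None = None,
) -> CalibrationFit:
    """Fit one cell's NB calibration regression.

    ``observed`` are per-species UMI counts aligned with ``expected``
    molecules per nucleus. Species with expected <= 0 are errors; observed
    zeros are retained (the NB likelihood handles them). Requires >= 3
    species. ``alpha`` fixes the dispersion instead of profiling it.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(expected, dtype=float)
    if y.shape != x.shape:
        raise ValueError("observed and expected must align")
    if np.any(x <= 0):
        raise ValueError("expected molecule counts must be > 0")
    z = int(round(y.sum()))
    n_det = int(np.sum(y > 0))
    if y.size < 3:
        return CalibrationFit(
            cell_barcode, np.nan, np.nan, np.nan, np.nan, z, n_det, False,
            error="fewer than 3 usable species",
        )
    X = np.column_stack([np.ones(y.size), np.log(x)])
    fit = fit_nb_glm(y, X, alpha=alpha)
    r2 = pseudo_r2(y, x, fit)
    return CalibrationFit(
        cell_barcode=cell_barcode,
        slope=float(fit.beta[1]),
        intercept=float(fit.beta[0]),
        dispersion=float(fit.alpha),
        pseudo_r2=float(r2),
        total_hash_umis=z,
        n_species_detected=n_det,
        converged=bool(fit.converged),
    )


_REASONS = ("fit_error", "low_r2", "low_hash_umis", "few_species", "not_converged")


def qc_filter(
    fits: list[CalibrationFit], config: QcConfig | None = None
) -> tuple[np.ndarray, list[list[str]]]:
    """Pass mask plus per-cell failure reasons.

    Reasons are drawn from {fit_error, low_r2, low_hash_umis, few_species,
    not_converged}; a passing cell gets an empty list.
    """
    if not fits:
        raise ValueError("no fits to filter")
    config = config or QcConfig()
    mask = np.zeros(len(fits), dtype=bool)
    reasons: list[list[str]] = []
    for i, f in enumerate(fits):
        r: list[str] = []
        if f.error is not None:
            r.append("fit_error")
        else:
            if not (f.pseudo_r2 >= config.r2_min):
                r.append("low_r2")
            if f.total_hash_umis < config.min_hash_umis:
                r.append("low_hash_umis")
            if f.n_species_detected < config.min_species:
                r.append("few_species")
            if not f.converged:
                r.append("not_converged")
        mask[i] = not r
        reasons.append(r)
    return mask, reasons


class CalibrationModel:
    """Per-cell calibration regressions over a hash count matrix.

    Parameters
    ----------
    hash_counts : HashCountMatrix
        cell x species UMI counts; only ladder-role species of ``ladder``
        are used (sample-ID hashes are considered separately by demux).
    ladder : LadderSpec
        The designed ladder; provides expected molecules per nucleus.
    """

    def __init__(self, hash_counts: HashCountMatrix, ladder: LadderSpec):
        self.ladder = ladder
        expected = expected_molecules_per_cell(ladder)
        keep = [s for s in hash_counts.species if s in expected]
        if len(keep) < 3:
            raise ValueError("count matrix shares < 3 species with the ladder")
        self.hash_counts = hash_counts.subset_species(keep)
        self.expected = np.array([expected[s] for s in keep])

    def fit(
        self, qc: QcConfig | None = None, alpha: float | None = None
    ) -> "CalibrationResults":
        qc = qc or QcConfig()
        dense = self.hash_counts.dense()
        fits = [
            fit_cell_calibration(dense[i], self.expected, cell_barcode=c, alpha=alpha)
            for i, c in enumerate(self.hash_counts.cells)
        ]
        mask, reasons = qc_filter(fits, qc)
        return CalibrationResults(self, fits, mask, reasons, qc)


class CalibrationResults:
    """Fitted calibration lines, QC outcome, and per-cell table."""

    def __init__(self, model, fits, qc_mask, qc_reasons, qc_config):
        self.model = model
        self.fits = fits
        self.qc_mask = np.asarray(qc_mask, dtype=bool)
        self.qc_reasons = qc_reasons
        self.qc_config = qc_config

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for f, ok, why in zip(self.fits, self.qc_mask, self.qc_reasons):
            rows.append(
                {
                    "cell_barcode": f.cell_barcode,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "dispersion": f.dispersion,
                    "pseudo_r2": f.pseudo_r2,
                    "total_hash_umis": f.total_hash_umis,
                    "n_species": f.n_species_detected,
                    "qc_pass": bool(ok),
                    "qc_reason": ";".join(why),
                }
            )
        return pd.DataFrame(rows)

    def passing(self) -> pd.DataFrame:
        t = self.table
        return t[t.qc_pass].reset_index(drop=True)

    def summary(self) -> str:
        t = self.table
        ok = t[t.qc_pass]
        lines = [
            "Hash-ladder calibration",
            "=" * 40,
            f"cells fit:            {len(t)}",
            f"cells passing QC:     {len(ok)} "
            f"({100 * len(ok) / max(len(t), 1):.1f}%)",
            f"QC: r2 >= {self.qc_config.r2_min}, "
            f"ladder UMIs >= {self.qc_config.min_hash_umis}, "
            f"species >= {self.qc_config.min_species}",
        ]
        if len(ok):
            lines += [
                f"median pseudo-R2:     {ok.pseudo_r2.median():.3f}",
                f"median slope:         {ok.slope.median():.3f}",
                f"median intercept:     {ok.intercept.median():.3f}",
                f"median ladder UMIs:   {ok.total_hash_umis.median():.0f}",
            ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
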