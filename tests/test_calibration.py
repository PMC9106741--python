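import numpy as np
import pytest
import statsmodels.api as sm

from hashladder._glm import fit_nb_glm, nb_deviance
from hashladder.calibration import (
    CalibrationFit,
    CalibrationModel,
    QcConfig,
    fit_cell_calibration,
    pseudo_r2,
    qc_filter,
)
from hashladder.hash_io import HashCountMatrix
from hashladder.ladder import expected_molecules_per_cell


@pytest.fixture
def expected6():
    # 6-point ten-fold ladder of expected molecules
    return np.geomspace(100, 1e7, 6)


class TestFitCellCalibration:
    def test_noiseless_power_law(self, expected6):
        observed = np.round(0.01 * expected6)
        fit = fit_cell_calibration(observed, expected6)
        # independent check: weighted least squares on the log scale
        wls = np.polyfit(np.log(expected6), np.log(observed), 1)
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.intercept == pytest.approx(np.log(0.01), abs=0.05)
        assert fit.slope == pytest.approx(wls[0], abs=0.05)

    def test_constant_observed_gives_zero_slope(self, expected6):
        fit = fit_cell_calibration(np.full(6, 50.0), expected6)
        assert abs(fit.slope) < 1e-6

    def test_too_few_species_flagged(self):
        fit = fit_cell_calibration([5, 6], [10.0, 100.0])
        assert fit.error is not None
        assert not np.isfinite(fit.slope)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            fit_cell_calibration([1, 2, 3], [0.0, 1.0, 2.0])

    def test_monte_carlo_recovery(self, ladder48, rng):
        expected = np.array(list(expected_molecules_per_cell(ladder48).values()))
        mu = np.exp(-5.0 + np.log(expected))
        slopes, intercepts = [], []
        for _ in range(60):
            y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu))
            f = fit_cell_calibration(y, expected)
            slopes.append(f.slope)
            intercepts.append(f.intercept)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)
        assert np.mean(intercepts) == pytest.approx(-5.0, abs=0.15)

    def test_agrees_with_statsmodels_oracle(self, ladder48, rng):
        expected = np.array(list(expected_molecules_per_cell(ladder48).values()))
        X = np.column_stack([np.ones(expected.size), np.log(expected)])
        mu = np.exp(-5.0 + np.log(expected))
        for _ in range(20):
            y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu)).astype(float)
            fit = fit_cell_calibration(y, expected)
            oracle = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=max(fit.dispersion, 1e-8))
            ).fit()
            assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-4)
            assert fit.slope == pytest.approx(oracle.params[1], abs=1e-4)

    def test_species_permutation_invariance(self, expected6, rng):
        y = rng.poisson(0.01 * expected6) + 1.0
        fit = fit_cell_calibration(y, expected6)
        perm = rng.permutation(6)
        fit_p = fit_cell_calibration(y[perm], expected6[perm])
        assert fit_p.slope == pytest.approx(fit.slope, abs=1e-8)
        assert fit_p.intercept == pytest.approx(fit.intercept, abs=1e-8)

    def test_expected_rescaling_shifts_intercept_only(self, expected6, rng):
        y = rng.poisson(0.01 * expected6) + 1.0
        base = fit_cell_calibration(y, expected6)
        scaled = fit_cell_calibration(y, 10.0 * expected6)
        assert scaled.slope == pytest.approx(base.slope, abs=1e-6)
        assert scaled.intercept == pytest.approx(
            base.intercept - base.slope * np.log(10.0), abs=1e-6
        )


class TestPseudoR2:
    def test_perfect_fit_reaches_one(self, expected6):
        y = np.round(0.01 * expected6)
        fit = fit_cell_calibration(y, expected6)
        assert fit.pseudo_r2 > 0.999

    def test_null_model_scores_zero(self, expected6):
        # slope constrained to zero: fit the intercept-only model directly
        y = np.array([40.0, 42.0, 38.0, 41.0, 39.0, 40.0])
        null = fit_nb_glm(y, np.ones((6, 1)))
        r2 = pseudo_r2(y, expected6, null)
        assert r2 == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_deviance_computation(self, expected6, rng):
        y = rng.poisson(0.02 * expected6).astype(float) + 1.0
        fit = fit_cell_calibration(y, expected6)
        X = np.column_stack([np.ones(6), np.log(expected6)])
        full = fit_nb_glm(y, X, alpha=fit.dispersion)
        null = fit_nb_glm(y, np.ones((6, 1)), alpha=fit.dispersion)
        d_model = nb_deviance(y, full.mu, fit.dispersion)
        d_null = nb_deviance(y, null.mu, fit.dispersion)
        assert fit.pseudo_r2 == pytest.approx(1 - d_model / d_null, abs=1e-8)

    def test_improves_with_counts_on_power_law(self, expected6, rng):
        r2s = []
        for scale in (0.0001, 0.01):
            y = rng.poisson(scale * expected6)
            f = fit_cell_calibration(y, expected6)
            r2s.append(f.pseudo_r2)
        assert r2s[1] > r2s[0] or r2s[1] > 0.99


class TestQcFilter:
    def mk(self, **kw):
        base = dict(
            cell_barcode="c", slope=1.0, intercept=-5.0, dispersion=0.1,
            pseudo_r2=0.95, total_hash_umis=3000, n_species_detected=48,
            converged=True,
        )
        base.update(kw)
        return CalibrationFit(**base)

    def test_boundary_cases(self):
        fits = [
            self.mk(pseudo_r2=0.69, total_hash_umis=5000),  # fail low_r2
            self.mk(pseudo_r2=0.95, total_hash_umis=99),    # fail low_hash_umis
            self.mk(total_hash_umis=3000, n_species_detected=9),  # fail few_species
            self.mk(pseudo_r2=0.70, total_hash_umis=100, n_species_detected=10),  # pass
        ]
        mask, reasons = qc_filter(fits, QcConfig())
        assert mask.tolist() == [False, False, False, True]
        assert reasons[0] == ["low_r2"]
        assert reasons[1] == ["low_hash_umis"]
        assert reasons[2] == ["few_species"]
        assert reasons[3] == []

    def test_multiple_reasons_reported(self):
        mask, reasons = qc_filter([self.mk(pseudo_r2=0.1, total_hash_umis=5)])
        assert not mask[0]
        assert set(reasons[0]) == {"low_r2", "low_hash_umis"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_filter([])


class TestCalibrationModel:
    def test_model_fit_table_and_summary(self, ladder48, rng):
        expected = np.array(list(expected_molecules_per_cell(ladder48).values()))
        species = [s.species_id for s in ladder48.ladder_species]
        counts = rng.poisson(0.005 * expected[None, :] * np.ones((30, 1)))
        m = HashCountMatrix([f"c{i}" for i in range(30)], species, counts)
        res = CalibrationModel(m, ladder48).fit()
        tab = res.table
        assert len(tab) == 30
        assert (tab.total_hash_umis == counts.sum(axis=1)).all()
        assert "median pseudo-R2" in res.summary()
        assert tab.qc_pass.mean() > 0.9

    def test_too_few_shared_species_rejected(self, ladder48):
        m = HashCountMatrix(["c0"], ["L00", "L01"], np.array([[1, 2]]))
        with pytest.raises(ValueError):
            CalibrationModel(m, ladder48)
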