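import dataclasses

import numpy as np
import pytest

from cosolv.datamodel import SolventBasis, UnitCode
from cosolv.model import (
    FitError,
    UnderdeterminedError,
    back_calculate,
    build_regression,
    fit_ja,
    predict_ln_solubility,
    yalkowsky_predict,
)
from cosolv.synth import GeneratorConfig, generate_dataset
from cosolv.units import convert_dataset

from conftest import J_SET_A


def normal_equations(y, X):
    """Independent brute-force OLS oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture
def conv(noise_free_dataset):
    return convert_dataset(noise_free_dataset, UnitCode(4))


@pytest.fixture
def conv_noisy(noisy_dataset):
    return convert_dataset(noisy_dataset, UnitCode(4))


class TestBuildRegression:
    def test_pure_solvent_rows_excluded(self, conv):
        y, X = build_regression(conv, 2)
        # 33 records, 6 anchors -> 27 mixed rows
        assert y.shape == (27,)
        assert X.shape == (27, 3)

    def test_equimolar_columns_vanish(self, conv):
        y, X = build_regression(conv, 4)
        rows = np.isclose(conv.w1[(conv.w1 > 0) & (conv.w1 < 1)], 0.5)
        assert np.all(X[rows, 1:] == 0.0)

    def test_noise_free_forward_consistency(self, conv):
        # oracle: the response of noise-free data equals design @ J exactly
        y, X = build_regression(conv, 2)
        np.testing.assert_allclose(y, X @ np.array(J_SET_A), rtol=1e-10)

    def test_underdetermined(self, drug, ethanol, water):
        from conftest import make_manual_dataset

        ds = make_manual_dataset(
            drug,
            ethanol,
            water,
            temperatures=(298.15,),
            w_grid=(0.0, 0.3, 0.5, 0.7, 1.0),
        )
        conv = convert_dataset(ds, UnitCode(4))
        # 3 mixed rows < 5 coefficients
        with pytest.raises(UnderdeterminedError):
            build_regression(conv, 4)

    def test_np_out_of_range(self, conv):
        with pytest.raises(ValueError):
            build_regression(conv, 5)


class TestFit:
    def test_recovers_generating_constants(self, conv):
        fit = fit_ja(conv, np_index=2)
        np.testing.assert_allclose(fit.coefficients, J_SET_A, rtol=1e-8)

    def test_all_zero_response_reduces_to_yalkowsky(self, drug, ethanol, water):
        from conftest import make_manual_dataset

        ds = make_manual_dataset(drug, ethanol, water)  # built on the ideal plane
        conv = convert_dataset(ds, UnitCode(4))
        fit = fit_ja(conv, np_index=2)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-9)

    def test_matches_normal_equations_small_system(self, drug, ethanol, water):
        from conftest import make_manual_dataset

        cfg = GeneratorConfig(
            j_true=(500.0, -200.0),
            composition_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            temperatures=(298.15,),
            noise_sigma=0.08,
            seed=42,
            drug=drug,
            solvent1=ethanol,
            solvent2=water,
        )
        conv = convert_dataset(generate_dataset(cfg), UnitCode(4))
        y, X = build_regression(conv, 1)
        fit = fit_ja(conv, np_index=1)
        np.testing.assert_allclose(
            fit.coefficients, normal_equations(y, X), rtol=1e-10
        )

    def test_rank_deficient_design(self, drug, ethanol, water):
        from conftest import make_manual_dataset

        # symmetric two-point mixed grid: (w1-w2)^2 is proportional to
        # (w1-w2)^0, so np=2 is collinear
        ds = make_manual_dataset(
            drug,
            ethanol,
            water,
            temperatures=(298.15, 308.15),
            w_grid=(0.0, 0.25, 0.75, 1.0),
        )
        conv = convert_dataset(ds, UnitCode(4))
        with pytest.raises(FitError, match="collinear"):
            fit_ja(conv, np_index=2)

    def test_nested_rss_monotone(self, conv_noisy):
        rss = []
        for np_i in range(0, 5):
            y, X = build_regression(conv_noisy, np_i)
            fit = fit_ja(conv_noisy, np_index=np_i)
            resid = y - X @ fit.coefficients
            rss.append(resid @ resid)
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_solvent_swap_symmetry(self, base_config):
        """Relabeling solvents 1<->2 flips the sign of odd-order terms."""
        ds = generate_dataset(base_config)
        swapped = dataclasses.replace(
            ds,
            solvent1=ds.solvent2,
            solvent2=ds.solvent1,
            records=[
                dataclasses.replace(r, solvent_fraction_1=1.0 - r.solvent_fraction_1)
                for r in ds.records
            ],
        )
        f1 = fit_ja(convert_dataset(ds, UnitCode(4)), np_index=2)
        f2 = fit_ja(convert_dataset(swapped, UnitCode(4)), np_index=2)
        signs = np.array([(-1.0) ** i for i in range(3)])
        np.testing.assert_allclose(f2.coefficients, signs * f1.coefficients, rtol=1e-6)

    def test_scale_invariance_of_coefficients(self, conv_noisy):
        scaled = dataclasses.replace(
            conv_noisy,
            x_m=conv_noisy.x_m * 37.5,
            x1_T=conv_noisy.x1_T * 37.5,
            x2_T=conv_noisy.x2_T * 37.5,
        )
        f1 = fit_ja(conv_noisy, np_index=2)
        f2 = fit_ja(scaled, np_index=2)
        np.testing.assert_allclose(f2.coefficients, f1.coefficients, rtol=1e-9)


class TestPruning:
    def test_prunes_null_high_order_term(self, base_config):
        cfg = dataclasses.replace(
            base_config, j_true=(*J_SET_A, 0.0), noise_sigma=0.05, seed=5
        )
        conv = convert_dataset(generate_dataset(cfg), UnitCode(4))
        fit = fit_ja(conv, np_index=3, prune=True, alpha=0.05)
        assert fit.retained.tolist() == [True, True, True, False]
        assert fit.coefficients[3] == 0.0
        assert np.isnan(fit.p_values[3])

    def test_retained_terms_significant(self, base_config):
        cfg = dataclasses.replace(base_config, noise_sigma=0.05, seed=9)
        conv = convert_dataset(generate_dataset(cfg), UnitCode(4))
        fit = fit_ja(conv, np_index=4, prune=True, alpha=0.05)
        assert np.all(fit.p_values[fit.retained] <= 0.05)

    def test_never_prunes_to_nothing(self, drug, ethanol, water):
        # pure-noise response: elimination must stop at one term
        cfg = GeneratorConfig(
            j_true=(0.0,),
            noise_sigma=0.5,
            seed=13,
            drug=drug,
            solvent1=ethanol,
            solvent2=water,
        )
        conv = convert_dataset(generate_dataset(cfg), UnitCode(4))
        fit = fit_ja(conv, np_index=2, prune=True, alpha=0.05)
        assert fit.retained.sum() >= 1


class TestPredict:
    def test_boundary_identities(self, conv):
        fit = fit_ja(conv, np_index=2)
        assert predict_ln_solubility(fit, 1.0, 298.2, -3.5, -8.0) == -3.5
        assert predict_ln_solubility(fit, 0.0, 298.2, -3.5, -8.0) == -8.0

    def test_zero_coefficients_give_yalkowsky(self):
        for w1 in (0.1, 0.5, 0.77):
            assert predict_ln_solubility(
                [0.0, 0.0, 0.0], w1, 310.0, -2.0, -9.0
            ) == pytest.approx(yalkowsky_predict(w1, -2.0, -9.0), rel=1e-14)

    def test_forward_hand_evaluation(self):
        # independent arithmetic oracle at (w1, T) = (0.3, 308.2)
        J = (934.547, -937.019, 1130.686, -1443.763, 848.997)
        w1, T, ln1, ln2 = 0.3, 308.2, -4.0, -7.0
        w2 = 1 - w1
        expected = w1 * ln1 + w2 * ln2 + (w1 * w2 / T) * sum(
            J[i] * (w1 - w2) ** i for i in range(5)
        )
        assert predict_ln_solubility(list(J), w1, T, ln1, ln2) == pytest.approx(
            expected, rel=1e-14
        )

    def test_yalkowsky_cases(self):
        assert yalkowsky_predict(0.5, -3.0, -3.0) == -3.0
        assert yalkowsky_predict(1.0, -3.0, -9.0) == -3.0
        assert yalkowsky_predict(0.25, -4.0, -8.0) == pytest.approx(-7.0)


class TestBackCalculate:
    def test_pure_solvent_records_exact(self, conv):
        fit = fit_ja(conv, np_index=2)
        bc = back_calculate(fit, conv)
        anchors = (conv.w1 == 0.0) | (conv.w1 == 1.0)
        np.testing.assert_array_equal(bc.x_cal[anchors], bc.x_exp[anchors])

    def test_noise_free_consistency(self, conv):
        fit = fit_ja(conv, np_index=2)
        bc = back_calculate(fit, conv)
        np.testing.assert_allclose(bc.x_cal, bc.x_exp, rtol=1e-10)

    def test_length(self, conv):
        fit = fit_ja(conv, np_index=2)
        assert len(back_calculate(fit, conv)) == len(conv)


class TestSerialization:
    def test_fit_to_dict_json_safe(self, conv):
        import json

        fit = fit_ja(conv, np_index=2)
        payload = json.dumps(fit.to_dict())
        back = json.loads(payload)
        assert back["np"] == 2
        assert back["code"] == 4
        assert len(back["coefficients_K"]) == 3
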