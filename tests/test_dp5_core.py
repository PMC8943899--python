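import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.interpolate import interp1d

import dp5
from dp5.dp5_core import GAS_CONSTANT_KJ
from dp5.exceptions import CalibrationError, DomainError


# ---------------------------------------------------------------------------
# Boltzmann weighting


def test_boltzmann_single_and_symmetric():
    assert dp5.boltzmann_weights([0.0]).weights.tolist() == [1.0]
    np.testing.assert_allclose(dp5.boltzmann_weights([0.0, 0.0]).weights,
                               [0.5, 0.5])


def test_boltzmann_rt_ln2_closed_form():
    T = 298.15
    w = dp5.boltzmann_weights([0.0, GAS_CONSTANT_KJ * T * np.log(2)], T).weights
    np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-10)


def test_boltzmann_validation():
    with pytest.raises(DomainError):
        dp5.boltzmann_weights([])
    with pytest.raises(DomainError):
        dp5.boltzmann_weights([0.0], temperature=-1.0)


def test_combine_conformers():
    w = dp5.boltzmann_weights([0.0])
    table = np.array([[0.3, 0.9]])
    np.testing.assert_allclose(dp5.combine_conformers(table, w), [0.3, 0.9])
    w2 = dp5.BoltzmannWeights(weights=np.array([0.5, 0.5]))
    np.testing.assert_allclose(
        dp5.combine_conformers(np.array([[0.2, 1.0], [0.8, 0.0]]), w2),
        [0.5, 0.5],
    )
    w10 = dp5.BoltzmannWeights(weights=np.array([1.0, 0.0]))
    np.testing.assert_allclose(
        dp5.combine_conformers(np.array([[0.2, 1.0], [0.8, 0.0]]), w10),
        [0.2, 1.0],
    )
    with pytest.raises(DomainError):
        dp5.combine_conformers(np.array([[0.2]]), w2)


# ---------------------------------------------------------------------------
# molecular probability contract


@settings(deadline=None, derandomize=True)
@given(st.floats(0.01, 1.0), st.integers(1, 12))
def test_molecular_probability_idempotent_on_constants(c, n):
    assert dp5.molecular_probability([c] * n) == pytest.approx(c, rel=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
def test_molecular_probability_symmetric_bounded_monotone(p):
    pn = dp5.molecular_probability(p)
    assert 0.0 <= pn <= 1.0
    assert dp5.molecular_probability(list(reversed(p))) == pytest.approx(pn)
    lowered = list(p)
    lowered[0] = lowered[0] / 2
    assert dp5.molecular_probability(lowered) <= pn + 1e-15


def test_molecular_probability_floors_and_errors():
    assert dp5.molecular_probability([0.0, 1.0]) == pytest.approx(1e-6, rel=1e-9)
    with pytest.raises(DomainError):
        dp5.molecular_probability([])


# ---------------------------------------------------------------------------
# calibration


def test_calibration_densities_integrate_to_one(rng):
    model = dp5.fit_calibration(rng.beta(5, 2, 300), rng.beta(2, 5, 300))
    for density in (model.density_correct, model.density_incorrect):
        f = interp1d(model.grid, density)
        area, _ = quad(f, model.grid[0], model.grid[-1], limit=400)
        # mass on the open interval covered by the grid
        assert area == pytest.approx(1.0, abs=2e-3)


def test_calibration_indistinguishable_classes_return_prior(rng):
    """Two draws from one distribution: the posterior stays at the prior
    over the region where the classes actually have mass."""
    samples = rng.beta(3, 3, size=400)
    model = dp5.fit_calibration(samples[:200], samples[200:])
    x = np.quantile(samples, np.linspace(0.05, 0.95, 50))
    post = np.array([dp5.dp5_probability(v, model) for v in x])
    # KDE-ratio sampling noise at 200/class keeps the posterior within ~0.1
    assert np.max(np.abs(post - 0.5)) < 0.1


def test_calibration_separated_classes(rng):
    correct = np.clip(rng.normal(0.7, 0.05, 400), 0.01, 0.99)
    incorrect = np.clip(rng.normal(0.1, 0.05, 400), 0.01, 0.99)
    model = dp5.fit_calibration(correct, incorrect)
    assert dp5.dp5_probability(0.7, model) > 0.9
    assert dp5.dp5_probability(0.1, model) < 0.1


def test_calibration_refuses_small_classes(rng):
    with pytest.raises(CalibrationError):
        dp5.fit_calibration(rng.uniform(size=10), rng.uniform(size=200))


def test_calibration_weighted_incorrect_shifts_density(rng):
    incorrect = np.concatenate([rng.uniform(0.0, 0.2, 200),
                                rng.uniform(0.6, 0.8, 200)])
    weights = np.concatenate([np.ones(200), np.zeros(200)])
    model = dp5.fit_calibration(rng.uniform(0.4, 0.6, 200), incorrect,
                                incorrect_weights=weights)
    # weighted-out mass near 0.7 means density there is ~floor
    assert model.f_incorrect(0.1) > 100 * model.f_incorrect(0.7)


def test_dp5_probability_bayes_identity_and_arithmetic():
    grid = (np.arange(512) + 0.5) / 512
    model = dp5.CalibrationModel(
        grid=grid,
        density_correct=np.full(512, 1.0),
        density_incorrect=np.full(512, 1.0),
        prior_correct=0.3,
    )
    assert dp5.dp5_probability(0.42, model) == pytest.approx(0.3)
    # tabulated hand computation: fc=2, fi=0.5, prior 0.5 -> 2/2.5
    model2 = dp5.CalibrationModel(
        grid=grid,
        density_correct=np.full(512, 2.0),
        density_incorrect=np.full(512, 0.5),
        prior_correct=0.5,
    )
    assert dp5.dp5_probability(0.9, model2) == pytest.approx(0.8, abs=1e-10)
    model3 = dp5.CalibrationModel(
        grid=grid,
        density_correct=np.full(512, 1.3),
        density_incorrect=np.full(512, 1e-300),
        prior_correct=0.5,
    )
    assert dp5.dp5_probability(0.5, model3) == pytest.approx(1.0)


def test_calibration_round_trip(tmp_path, rng):
    model = dp5.fit_calibration(rng.beta(5, 2, 100), rng.beta(2, 5, 100))
    path = tmp_path / "calib.h5"
    model.save(path)
    back = dp5.CalibrationModel.load(path)
    np.testing.assert_array_equal(back.grid, model.grid)
    np.testing.assert_array_equal(back.density_correct, model.density_correct)
    assert back.prior_correct == model.prior_correct


# ---------------------------------------------------------------------------
# full pipeline


def test_run_dp5_zero_error_dominates_perturbed(small_corpus, small_db):
    corpus, _ = small_corpus
    mol, _ = corpus[0]
    idx = mol.carbon_indices
    exact = dp5.PeakList(shifts=mol.carbon_shifts(0).copy())
    res_exact = dp5.run_dp5(mol, exact, small_db,
                            exclude_molecule=mol.molecule_id)
    rng = np.random.default_rng(0)
    perturbed = dp5.PeakList(shifts=mol.carbon_shifts(0) + rng.normal(0, 6, idx.size))
    res_pert = dp5.run_dp5(mol, perturbed, small_db,
                           exclude_molecule=mol.molecule_id)
    assert res_exact.molecular_probability >= res_pert.molecular_probability
    assert np.all(res_exact.atomic_probabilities >= 0)
    assert np.all(res_exact.atomic_probabilities <= 1)


def test_run_dp5_deterministic(small_corpus, small_db):
    corpus, _ = small_corpus
    mol, peaks = corpus[1]
    r1 = dp5.run_dp5(mol, peaks, small_db, exclude_molecule=mol.molecule_id)
    r2 = dp5.run_dp5(mol, peaks, small_db, exclude_molecule=mol.molecule_id)
    assert r1.molecular_probability == r2.molecular_probability
    np.testing.assert_array_equal(r1.atomic_probabilities, r2.atomic_probabilities)
    np.testing.assert_array_equal(r1.diagnostics, r2.diagnostics)
    assert r1.to_json() == r2.to_json()


def test_run_dp5_leave_one_out_equals_removed_database(small_corpus):
    """Excluding a molecule must equal scoring against a db built without it."""
    corpus, _ = small_corpus
    params = dp5.DescriptorParams()
    full = dp5.build_error_database(corpus, params, seed=9)
    mol, peaks = corpus[2]
    reduced = dp5.build_error_database(
        [c for c in corpus if c[0].molecule_id != mol.molecule_id],
        params, sigma=full.sigma, seed=9,
    )
    reduced.eps_star = full.eps_star  # hold the integration window fixed
    r_excl = dp5.run_dp5(mol, peaks, full, exclude_molecule=mol.molecule_id)
    r_red = dp5.run_dp5(mol, peaks, reduced, exclude_molecule=None)
    # zero-weighted records contribute nothing: the bespoke PDFs coincide
    np.testing.assert_allclose(
        r_excl.atomic_probabilities, r_red.atomic_probabilities, atol=1e-9
    )


def test_end_to_end_error_inflation_never_increases_pn(small_corpus, small_db):
    corpus, _ = small_corpus
    mol, _ = corpus[3]
    shifts = mol.carbon_shifts(0)
    rng = np.random.default_rng(1)
    base_err = rng.normal(0, 1.0, size=shifts.size)
    last = None
    for factor in (1.0, 2.0, 4.0):
        peaks = dp5.PeakList(shifts=shifts - factor * base_err)
        res = dp5.run_dp5(mol, peaks, small_db, exclude_molecule=mol.molecule_id)
        if last is not None:
            assert res.molecular_probability <= last + 1e-9
        last = res.molecular_probability
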