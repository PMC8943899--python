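import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gaussian_kde

import dp5
from dp5.error_model import _weighted_silverman
from dp5.exceptions import DomainError


def _peaks(values, counts=None):
    return dp5.PeakList(shifts=np.array(values, dtype=float),
                        multiplicities=None if counts is None else np.array(counts))


# ---------------------------------------------------------------------------
# assignment


def test_assignment_simple_swap():
    a = dp5.assign_peaks(np.array([20.0, 120.0]), _peaks([119.0, 21.0]))
    assert a.mapping == {0: 21.0, 1: 119.0}
    assert a.cost == pytest.approx(2.0)
    assert a.unassigned_atoms == []


def test_assignment_identical_zero_cost():
    shifts = np.array([10.0, 50.0, 90.0])
    a = dp5.assign_peaks(shifts, _peaks(shifts))
    assert a.cost == 0.0


def test_assignment_multiplicity_expansion():
    a = dp5.assign_peaks(np.array([20.0, 20.5]), _peaks([20.2], counts=[2]))
    assert a.unassigned_atoms == []
    assert set(a.mapping.values()) == {20.2}


def _brute_force_cost(shifts, slots):
    best = np.inf
    k = min(len(shifts), len(slots))
    for atoms in itertools.combinations(range(len(shifts)), k):
        for perm in itertools.permutations(range(len(slots)), k):
            cost = sum(abs(shifts[a] - slots[p]) for a, p in zip(atoms, perm))
            best = min(best, cost)
    return best


@pytest.mark.parametrize("n_atoms,n_peaks", [(3, 3), (4, 3), (5, 6), (6, 4)])
def test_assignment_matches_brute_force(n_atoms, n_peaks, rng):
    for _ in range(50):
        shifts = rng.uniform(0, 200, size=n_atoms)
        peaks = rng.uniform(0, 200, size=n_peaks)
        a = dp5.assign_peaks(shifts, _peaks(peaks))
        assert a.cost == pytest.approx(_brute_force_cost(shifts, np.sort(peaks)))
        assert len(a.unassigned_atoms) == max(0, n_atoms - n_peaks)


def test_assignment_empty_inputs():
    with pytest.raises(DomainError):
        dp5.assign_peaks(np.array([]), _peaks([1.0]))
    with pytest.raises(DomainError):
        dp5.PeakList(shifts=np.array([]))


# ---------------------------------------------------------------------------
# internal scaling


def test_scaling_removes_exact_linear_error():
    calc = np.array([10.0, 50.0, 90.0, 130.0])
    exp = 1.05 * calc - 2.0
    a = dp5.assign_peaks(calc, _peaks(exp))
    deltas = dp5.scale_errors(a, dict(enumerate(calc)))
    assert all(abs(d) < 1e-9 for d in deltas.values())


def test_scaling_outlier_matches_closed_form_residual():
    calc = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
    exp = calc.copy()
    exp[2] += 3.0  # one outlier
    mapping = {i: float(e) for i, e in enumerate(exp)}
    assignment = dp5.Assignment(mapping=mapping, unassigned_atoms=[], cost=3.0)
    deltas = dp5.scale_errors(assignment, dict(enumerate(calc)))
    # independent simple-regression residuals: delta = fitted - observed
    x, y = calc, exp
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = y.mean() - slope * x.mean()
    expected = slope * x + intercept - y
    for i in range(5):
        assert deltas[i] == pytest.approx(expected[i], abs=1e-12)


def test_scaling_two_atom_fallback_unscaled(caplog):
    mapping = {0: 12.0, 1: 55.0}
    assignment = dp5.Assignment(mapping=mapping, unassigned_atoms=[], cost=0.0)
    with caplog.at_level("WARNING"):
        deltas = dp5.scale_errors(assignment, {0: 10.0, 1: 50.0})
    assert deltas == {0: -2.0, 1: -5.0}  # calc - exp, no fit
    assert "unscaled" in caplog.text


# ---------------------------------------------------------------------------
# weighted KDE and atomic probability


def _pdf_from(errors, weights, bandwidth):
    params = dp5.DescriptorParams(n_radial_bins=1, elements=("C",))
    db = dp5.ErrorDatabase(
        descriptors=np.zeros((len(errors), 1)),
        errors=np.asarray(errors, dtype=float),
        molecule_ids=np.array([f"m{i}" for i in range(len(errors))], dtype=object),
        params=params,
    )
    return dp5.build_atomic_pdf(np.asarray(weights, dtype=float), db,
                                bandwidth=bandwidth)


def test_pdf_symmetric_support_gives_symmetric_density():
    pdf = _pdf_from([-1.0, 0.0, 1.0], [1.0, 1.0, 1.0], 0.5)
    x = np.linspace(0.0, 3.0, 50)
    assert np.max(np.abs(pdf.pdf(x) - pdf.pdf(-x))) < 1e-12


def test_pdf_single_record_is_one_gaussian():
    pdf = _pdf_from([2.0, 5.0], [1.0, 0.0], 0.3)
    x = np.linspace(0, 4, 30)
    expected = np.exp(-0.5 * ((x - 2.0) / 0.3) ** 2) / (0.3 * np.sqrt(2 * np.pi))
    np.testing.assert_allclose(pdf.pdf(x), expected, atol=1e-12)


def test_pdf_integrates_to_one_random_weights(rng):
    for _ in range(5):
        errors = rng.normal(0, 2, size=40)
        weights = rng.uniform(0, 1, size=40)
        pdf = _pdf_from(errors, weights, 0.4)
        area, _ = quad(pdf.pdf, -30, 30, limit=200)
        assert area == pytest.approx(1.0, abs=1e-6)
        assert pdf.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_uniform_weights_match_reference_kde(rng):
    errors = rng.normal(0, 1.5, size=60)
    h = 0.45
    pdf = _pdf_from(errors, np.ones(60), h)
    ref = gaussian_kde(errors, bw_method=h / errors.std(ddof=1))
    x = np.linspace(-5, 5, 100)
    np.testing.assert_allclose(pdf.pdf(x), ref(x), atol=1e-8)


def test_silverman_floor_on_single_weight(caplog):
    with caplog.at_level("WARNING"):
        pdf = _pdf_from([1.0, 2.0], [1.0, 0.0], "auto")
    assert pdf.bandwidth == pytest.approx(0.1)


def test_atomic_probability_normal_window_095():
    # dense normal quantiles + tiny bandwidth ~ standard normal density
    q = (np.arange(20000) + 0.5) / 20000
    from scipy.stats import norm

    errors = norm.ppf(q)
    pdf = _pdf_from(errors, np.ones_like(errors), 0.02)
    p = dp5.atomic_probability(pdf, 0.0, eps_star=1.96)
    assert p == pytest.approx(0.95, abs=2e-3)
    assert dp5.atomic_probability(pdf, 0.0, eps_star=1.96, scheme="two_tail") == 1.0


@pytest.mark.parametrize("scheme", ["window", "two_tail"])
def test_atomic_probability_matches_quadrature(scheme, rng):
    for _ in range(20):
        n = int(rng.integers(5, 30))
        errors = rng.standard_t(df=5, size=n) * rng.uniform(0.5, 3)
        weights = rng.uniform(0, 1, size=n)
        bw = rng.uniform(0.15, 1.0)
        pdf = _pdf_from(errors, weights, bw)
        delta = float(rng.normal(0, 3))
        eps = float(rng.uniform(0.5, 3))
        p = dp5.atomic_probability(pdf, delta, eps, scheme=scheme)
        if scheme == "window":
            oracle, _ = quad(pdf.pdf, delta - eps, delta + eps, limit=400)
        else:
            inner, _ = quad(pdf.pdf, -abs(delta), abs(delta), limit=400)
            oracle = 1 - inner
        assert p == pytest.approx(oracle, abs=1e-6)


def test_atomic_probability_window_continuity(rng):
    errors = rng.normal(0, 1, size=50)
    pdf = _pdf_from(errors, np.ones(50), 0.3)
    base = dp5.atomic_probability(pdf, 0.7, 1.5)
    nudged = dp5.atomic_probability(pdf, 0.7 + 1e-6, 1.5)
    assert abs(base - nudged) < 1e-4
    with pytest.raises(DomainError):
        dp5.atomic_probability(pdf, np.nan, 1.5)


def test_environment_conditioning_two_clusters():
    """Identical |error| must be less probable in a tight-error environment."""
    spec = dp5.SyntheticSpec(
        n_clusters=2, cluster_locations=(0.0, 0.0), cluster_scales=(1.0, 5.0),
        cluster_base_shifts=(20.0, 120.0), cluster_df=50.0, seed=7,
    )
    db, labels = dp5.make_clustered_database(3000, spec, seed=7)
    kp = dp5.KernelParams(sigma=db.sigma)
    probs = {}
    for k in (0, 1):
        centre = db.descriptors[labels == k].mean(axis=0)
        test = dp5.EnvironmentDescriptor(centre, "C", db.params.params_hash)
        w = dp5.kernel_weights(test, db, kp)
        pdf = dp5.build_atomic_pdf(w, db)
        probs[k] = dp5.atomic_probability(pdf, 4.0, db.eps_star)
    assert probs[0] < probs[1]


# ---------------------------------------------------------------------------
# database construction


def test_database_counts_eps_star_and_round_trip(small_corpus, tmp_path):
    corpus, _ = small_corpus
    db = dp5.build_error_database(corpus, dp5.DescriptorParams(), seed=5)
    n_carbons = sum(len(m.carbon_indices) for m, _ in corpus)
    assert len(db) == n_carbons
    assert db.eps_star == pytest.approx(np.mean(np.abs(db.errors)))
    path = tmp_path / "db.h5"
    db.save(path)
    back = dp5.ErrorDatabase.load(path)
    np.testing.assert_array_equal(back.descriptors, db.descriptors)
    np.testing.assert_array_equal(back.errors, db.errors)
    assert list(back.molecule_ids) == list(db.molecule_ids)
    assert back.eps_star == db.eps_star
    assert back.sigma == db.sigma
    assert back.params == db.params


def test_eps_star_mean_absolute():
    params = dp5.DescriptorParams(n_radial_bins=1, elements=("C",))
    db = dp5.ErrorDatabase(
        descriptors=np.zeros((4, 1)), errors=np.array([1.0, -1.0, 2.0, -2.0]),
        molecule_ids=np.array(list("abcd"), dtype=object), params=params,
    )
    assert db.eps_star == pytest.approx(1.5)
    with pytest.raises(DomainError):
        dp5.ErrorDatabase(
            descriptors=np.zeros((2, 1)), errors=np.array([1.0, -1.0]),
            molecule_ids=np.array(list("ab"), dtype=object), params=params,
            eps_star=9.9,
        )
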