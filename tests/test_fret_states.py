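"""Corrected efficiencies and Gaussian mixture state inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dimerstate as ds
from dimerstate import fret_states as F
from dimerstate.calibrate import CorrectionSet
from .conftest import make_burst


# ----------------------------------------------------------- efficiency

def test_proximity_ratio_case():
    e = F.burst_efficiency(make_burst(f_dd=30, f_da=70), CorrectionSet())
    assert e == pytest.approx(0.7)


def test_crosstalk_corrected_efficiency_by_direct_substitution():
    # F_corr = 70 - 0.1*30 - 0.1*50 = 62; E = 62/(62+30)
    cs = CorrectionSet(Lk=0.1, Di=0.1, gamma=1.0)
    e = F.burst_efficiency(make_burst(f_dd=30, f_da=70, f_aa=50), cs)
    assert e == pytest.approx(62 / 92)


def test_no_transfer_limit():
    assert F.burst_efficiency(make_burst(f_dd=40, f_da=0)) == 0.0


def test_nonpositive_denominator_discards_with_warning():
    cs = CorrectionSet(Lk=0.5, Di=0.5)
    bad = make_burst(f_dd=1, f_da=1, f_aa=100)
    with pytest.warns(UserWarning, match="discarded"):
        assert F.burst_efficiency(bad, cs) is None
    es = F.efficiencies([bad, make_burst(f_dd=30, f_da=70)], CorrectionSet())
    assert es.n_bursts == 2  # identity corrections keep both


# ------------------------------------------------------------- mixture

def _two_state_sample(rng, n=2500, means=(0.30, 0.62), sigmas=(0.08, 0.08), w1=0.58):
    n1 = rng.binomial(n, w1)
    return np.concatenate(
        [rng.normal(means[0], sigmas[0], n1), rng.normal(means[1], sigmas[1], n - n1)]
    )


def test_em_recovers_two_state_parameters(rng):
    x = _two_state_sample(rng, n=5000)
    m = ds.fit_mixture(x, K=2, random_state=0)
    assert m.converged
    assert m.means == pytest.approx([0.30, 0.62], abs=0.03)
    assert m.weights[0] == pytest.approx(0.58, abs=0.05)


def test_bic_selects_two_states(rng):
    x = _two_state_sample(rng, n=3000)
    m = ds.fit_mixture(x, K="auto", random_state=0)
    assert m.K == 2


def test_degenerate_identical_values_collapse_to_single_state():
    x = np.full(500, 0.4)
    m = ds.fit_mixture(x, K="auto", random_state=0)
    assert m.K == 1
    assert m.weights == pytest.approx([1.0])
    assert m.sigmas[0] == pytest.approx(0.01)  # at the floor


def test_em_loglik_monotone_and_weights_normalized(rng):
    x = _two_state_sample(rng, n=1200)
    est = F.FretMixture(n_components=2, random_state=1).fit(x)
    ll = est.ll_path_
    assert np.all(np.diff(ll) >= -1e-9 * (np.abs(ll[:-1]) + 1.0))
    assert est.weights_.sum() == pytest.approx(1.0, abs=1e-9)
    assert x.min() <= est.means_.min() <= est.means_.max() <= x.max()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_mixture_invariants_hold_for_arbitrary_samples(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-0.1, 1.1, 300)
    m = ds.fit_mixture(x, K=2, n_init=3, random_state=0)
    assert m.weights.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(m.sigmas > 0)
    assert np.all(np.diff(m.means) >= 0)
    assert x.min() - 1e-9 <= m.means[0] and m.means[-1] <= x.max() + 1e-9


def test_em_agrees_with_sklearn_reference(rng):
    from sklearn.mixture import GaussianMixture

    x = _two_state_sample(rng, n=3000)
    ours = ds.fit_mixture(x, K=2, random_state=0)
    ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-6).fit(x[:, None])
    order = np.argsort(ref.means_.ravel())
    assert ours.means == pytest.approx(ref.means_.ravel()[order], abs=0.01)
    assert ours.weights == pytest.approx(ref.weights_[order], abs=0.01)


def test_weight_recovery_median_error_across_seeds():
    # over 20 seeds at 5000 bursts, median |weight error| < 0.03
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        x = _two_state_sample(rng, n=5000)
        m = ds.fit_mixture(x, K=2, n_init=5, random_state=0)
        errs.append(abs(m.weights[0] - 0.58))
    assert np.median(errs) < 0.03


def test_state_population_labels_and_bootstrap(rng):
    x = _two_state_sample(rng, n=4000)
    m = ds.fit_mixture(x, K=2, random_state=0)
    pops = F.state_populations(m, E_values=x, n_boot=100, random_state=0)
    assert pops["state1"] == pytest.approx(0.58, abs=0.05)
    assert pops["state1"] + pops["state2"] == pytest.approx(1.0, abs=1e-6)
    assert 0 < pops["se"]["state1"] < 0.02
    inverted = F.state_populations(m, invert=True, n_boot=0)
    assert inverted["state1"] == pytest.approx(pops["state2"], abs=1e-9)


def test_symmetric_mixture_gives_equal_states(rng):
    x = _two_state_sample(rng, n=4000, w1=0.5)
    m = ds.fit_mixture(x, K=2, random_state=0)
    pops = F.state_populations(m, E_values=x, n_boot=100, random_state=0)
    assert abs(pops["state1"] - pops["state2"]) < 4 * pops["se"]["state1"] + 0.02


def test_fixed_components_refit_only_weights(rng):
    x = _two_state_sample(rng, n=2000)
    m = ds.fit_mixture(x, K=2, random_state=0)
    x2 = _two_state_sample(rng, n=2000, w1=0.8)
    w = F.refit_weights(m, x2)
    assert w[0] == pytest.approx(0.8, abs=0.05)
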