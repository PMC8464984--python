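"""Generator-level checks: the synthetic photon streams must actually have
the statistical structure the downstream analysis assumes."""

import dataclasses

import numpy as np
import pytest

import dimerstate as ds
from dimerstate.exceptions import ConfigurationError
from dimerstate.simulate import isotherm_fraction


def pure_species_config(kind, true_E=0.0, **kw):
    defaults = dict(duration=60.0, seed=4)
    defaults.update(kw)
    return ds.SimConfig(species=[ds.SpeciesSpec("x", kind, true_E, 1.0)], **defaults)


@pytest.mark.parametrize("true_E", [0.2, 0.5, 0.8])
def test_proximity_ratio_unbiased_without_distortions(true_E):
    # gamma=1, Lk=Di=0: mean per-burst proximity ratio equals the true E
    cfg = pure_species_config("doubly-labeled", true_E, duration=150.0)
    stream = ds.simulate_bursts(cfg)
    t = stream.truth
    dex = t.f_dd + t.f_da
    ok = dex >= 20
    pr = (t.f_da[ok] / dex[ok]).to_numpy()
    n_dex = dex[ok].mean()
    se = np.sqrt(true_E * (1 - true_E) / n_dex / ok.sum())
    assert abs(pr.mean() - true_E) < 3.5 * se


def test_leakage_shows_up_as_da_fraction_of_dd():
    cfg = pure_species_config("donor-only", duration=120.0)
    cfg = dataclasses.replace(cfg, leakage_Lk=0.1, background_rates=(0.0, 0.0, 0.0))
    stream = ds.simulate_bursts(cfg)
    t = stream.truth
    ratio = t.f_da.sum() / t.f_dd.sum()
    assert ratio == pytest.approx(0.1, rel=0.1)
    # a donor-only molecule emits nothing under acceptor excitation
    assert t.f_aa.sum() == 0


def test_two_state_truth_fractions_match_configured_populations():
    cfg = ds.two_state_config((0.30, 0.62), low_fraction=0.58, doubly_fraction=1.0,
                              donor_only_fraction=0.0, seed=9, duration=300.0)
    stream = ds.simulate_bursts(cfg)
    t = stream.truth
    frac = (t.label == "state1").mean()
    n = len(t)
    assert abs(frac - 0.58) < 3.5 * np.sqrt(0.58 * 0.42 / n)


def test_titration_weights_follow_one_site_isotherm():
    kd = 50e-9
    cfg = ds.two_state_config(seed=3, duration=10.0)
    conc = [0.0, kd / 10, kd, 10 * kd, 100 * kd]
    streams = ds.simulate_titration(cfg, conc, kd, enriched_label="state1", w_max=0.95)
    w = [s.meta["true_enriched_weight"] for s in streams]
    assert w[0] == pytest.approx(0.58, abs=1e-12)              # zero-ligand limit
    assert w[2] == pytest.approx((0.58 + 0.95) / 2, abs=1e-12)  # half saturation at L = KD
    assert w[4] == pytest.approx(0.95, rel=0.01)                # saturation limit
    expected = isotherm_fraction(np.asarray(conc), kd, 0.58, 0.95)
    assert np.allclose(w, expected, atol=1e-12)


def test_background_counts_are_poisson():
    # signal-free stream: per-bin variance/mean within [0.9, 1.1] at >= 1e5 bins
    cfg = ds.SimConfig(
        species=[ds.SpeciesSpec("x", "doubly-labeled", 0.5, 1.0)],
        burst_rate=0.0, duration=120.0, background_rates=(400.0, 300.0, 200.0), seed=8,
    )
    stream = ds.simulate_bursts(cfg)
    trace = ds.bin_photons(stream, 1e-3)
    assert trace.n_bins >= 1e5
    for counts in (trace.f_dd, trace.f_da, trace.f_aa):
        ratio = counts.var() / counts.mean()
        assert 0.9 < ratio < 1.1


def test_same_seed_gives_identical_stream():
    cfg = ds.two_state_config(seed=17, duration=20.0)
    a = ds.simulate_bursts(cfg)
    b = ds.simulate_bursts(cfg)
    assert np.array_equal(a.timestamps, b.timestamps)
    assert np.array_equal(a.excitation, b.excitation)
    assert np.array_equal(a.channel, b.channel)


def test_ruler_streams_share_corrections_and_emit_controls():
    cfg = ds.two_state_config(seed=5, duration=30.0, gamma=1.0)
    rulers = ds.simulate_rulers(cfg, [0.2, 0.8])
    assert len(rulers.doubly) == 2
    # gamma=1: apparent stoichiometry from truth counts is E-independent
    s_vals = []
    for st in rulers.doubly:
        t = st.truth
        s_vals.append((t.f_dd.sum() + t.f_da.sum()) / (t.f_dd.sum() + t.f_da.sum() + t.f_aa.sum()))
    assert abs(s_vals[0] - s_vals[1]) < 0.02
    # donor-only control: stoichiometry ~ 1 (no acceptor photons under Aex)
    td = rulers.donor_only.truth
    assert td.f_aa.sum() == 0


def test_fcs_pair_channels_and_decorrelation():
    stream = ds.simulate_fcs_pair(mean_rates=(2000.0, 2000.0), correlation_time=1e-3,
                                  contrast=0.0, duration=10.0, seed=6)
    na = stream.select("A", "A").size
    nd = stream.select("D", "D").size
    assert na + nd == stream.n_photons
    assert na == pytest.approx(2000 * 10, rel=0.1)


@pytest.mark.parametrize(
    "bad_call",
    [
        lambda: ds.simulate_bursts(ds.SimConfig(species=[], duration=1.0)),
        lambda: ds.simulate_bursts(
            ds.SimConfig(species=[ds.SpeciesSpec("x")], duration=-1.0)
        ),
        lambda: ds.simulate_titration(ds.two_state_config(), [1e-9], kd=-1.0),
        lambda: ds.simulate_rulers(ds.two_state_config(), [0.5]),
        lambda: ds.simulate_saxs_curve("sphere", {"radius": -3.0}),
        lambda: ds.simulate_fcs_pair(correlation_time=0.0),
        lambda: ds.SpeciesSpec("x", "mystery"),
    ],
)
def test_invalid_configurations_raise(bad_call):
    with pytest.raises(ConfigurationError):
        bad_call()
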