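"""Binning, background/threshold, burst search and PIE sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dimerstate as ds
from dimerstate import bursts as B
from dimerstate.calibrate import CorrectionSet
from .conftest import make_trace

# ---------------------------------------------------------------- binning

def _stream(times_ms, exc, ch):
    t = np.asarray(times_ms) * 1e-3
    return ds.PhotonStream(t, np.array(list(exc)), np.array(list(ch)),
                           meta={"duration": float(t[-1]) if t.size else 0.0})


def test_binning_assigns_photons_by_floor_division():
    s = _stream([0.2, 0.7, 1.5], "DDD", "DDD")
    trace = B.bin_photons(s, 1e-3)
    assert trace.f_dd.tolist() == [2, 1]
    assert trace.f_da.sum() == 0 and trace.f_aa.sum() == 0


def test_binning_empty_stream_gives_empty_trace():
    s = ds.PhotonStream(np.empty(0), np.empty(0, "U1"), np.empty(0, "U1"))
    trace = B.bin_photons(s, 1e-3)
    assert trace.n_bins == 0


def test_binning_conserves_photons_including_discarded_class():
    rng = np.random.default_rng(0)
    n = 100_000
    t = np.sort(rng.uniform(0, 50.0, n))
    exc = rng.choice(["D", "A"], n)
    ch = rng.choice(["D", "A"], n)
    s = ds.PhotonStream(t, exc, ch, meta={"duration": 50.0})
    trace = B.bin_photons(s, 1e-3)
    total = trace.f_dd.sum() + trace.f_da.sum() + trace.f_aa.sum() + trace.n_discarded
    assert total == n


# ------------------------------------------------- background & threshold

@pytest.mark.parametrize("rate,expected_thr", [(1.0, 3), (4.0, 7)])
def test_threshold_clamped_to_3_7_window(rate, expected_thr, rng):
    counts = rng.poisson(rate, 20000)
    trace = B.BinnedTrace(1e-3, counts, counts.copy(), counts.copy())
    trace = B.estimate_background(trace)
    assert trace.threshold[0] == expected_thr
    assert trace.background[0] == pytest.approx(rate, rel=0.05)


def test_all_zero_trace_background_zero_threshold_floor():
    z = np.zeros(2000, dtype=np.int64)
    trace = B.estimate_background(B.BinnedTrace(1e-3, z, z.copy(), z.copy()))
    assert trace.background[0] == 0.0
    assert trace.threshold.tolist() == [3, 3, 3]


def test_background_unbiased_in_presence_of_bursts():
    # sparse bright bursts must be clipped out of the background estimate
    cfg = ds.two_state_config(seed=2, duration=120.0, background_rates=(300.0, 300.0, 300.0))
    trace = B.bin_photons(ds.simulate_bursts(cfg), 1e-3)
    trace = B.estimate_background(trace)
    assert trace.background[2] == pytest.approx(0.3, rel=0.15)  # AA: background only + bursts


def test_too_few_bins_rejected():
    z = np.zeros(10, dtype=np.int64)
    with pytest.raises(ValueError, match="bins"):
        B.estimate_background(B.BinnedTrace(1e-3, z, z.copy(), z.copy()))


# ---------------------------------------------------------- burst search

def test_single_run_detected_with_summed_counts():
    trace = make_trace([0, 5, 6, 7, 0])
    found = B.find_bursts(trace, threshold=4)
    assert len(found) == 1
    b = found[0]
    assert (b.start_bin, b.end_bin) == (1, 3)
    assert b.f_dd == 18


def test_adjacent_runs_not_merged_at_default_gap():
    trace = make_trace([5, 0, 5])
    assert len(B.find_bursts(trace, threshold=4)) == 2
    assert len(B.find_bursts(trace, threshold=4, merge_gap=2)) == 1


def _oracle_runs(x, thr):
    """Exhaustive enumeration of maximal above-threshold runs."""
    runs, start = [], None
    for i, v in enumerate(x):
        if v >= thr and start is None:
            start = i
        elif v < thr and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(x) - 1))
    return runs


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=50),
    st.integers(min_value=1, max_value=10),
)
def test_burst_finder_matches_exhaustive_run_enumeration(counts, thr):
    trace = make_trace(counts)
    found = [(b.start_bin, b.end_bin) for b in B.find_bursts(trace, threshold=thr)]
    assert found == _oracle_runs(np.asarray(counts), thr)


def test_burst_count_monotone_in_threshold(rng):
    # isolated bursts over quiet background: lowering the threshold can only
    # add bursts, never merge them (merging requires bridging bins at or
    # above the lower threshold, which a zero-background gap rules out)
    counts = np.zeros(3000, dtype=np.int64)
    idx = rng.choice(np.arange(1, 2999, 3), 400, replace=False)
    counts[idx] = rng.integers(1, 15, 400)
    trace = make_trace(counts)
    ns = [len(B.find_bursts(trace, threshold=thr)) for thr in (1, 3, 5, 8, 12)]
    assert all(a >= b for a, b in zip(ns, ns[1:]))
    assert ns[0] > ns[-1] > 0


def test_burst_search_idempotent(rng):
    counts = rng.poisson(3.0, 2000)
    trace = make_trace(counts)
    a = B.find_bursts(trace, threshold=5)
    b = B.find_bursts(trace, threshold=5)
    assert [(x.start_bin, x.end_bin, x.f_dd) for x in a] == [
        (x.start_bin, x.end_bin, x.f_dd) for x in b
    ]


def test_burst_raw_counts_bounded_by_stream_total():
    cfg = ds.two_state_config(seed=6, duration=30.0)
    stream = ds.simulate_bursts(cfg)
    trace = B.estimate_background(B.bin_photons(stream, 1e-3))
    found = B.find_bursts(trace)
    assert sum(b.f_dd + b.f_da + b.f_aa for b in found) <= stream.n_photons


def test_detection_recovers_bright_truth_bursts():
    cfg = ds.two_state_config(seed=7, duration=120.0)
    stream = ds.simulate_bursts(cfg)
    trace = B.estimate_background(B.bin_photons(stream, 1e-3))
    found = B.find_bursts(trace)
    thr = max(trace.threshold[0], trace.threshold[1])
    intervals = [(b.start_bin * 1e-3, (b.end_bin + 1) * 1e-3) for b in found]
    starts = np.array([iv[0] for iv in intervals])
    stops = np.array([iv[1] for iv in intervals])
    t = stream.truth
    bright = t[(t.f_dd + t.f_da) >= 2 * thr * 3]  # expected size >= 2x threshold over ~3 bins
    hit = 0
    for _, row in bright.iterrows():
        if np.any((starts < row.stop) & (stops > row.start)):
            hit += 1
    assert hit / len(bright) >= 0.95


# ------------------------------------------------------------ selection

def test_selection_boundary_at_25_photons(burst_factory):
    below = burst_factory(f_dd=12, f_da=12, f_aa=20)
    at = burst_factory(f_dd=13, f_da=12, f_aa=20)
    kept = B.select_and_sort([below, at])
    assert kept == [at]


def test_no_acceptor_signal_classified_donor_only(burst_factory):
    b = burst_factory(f_dd=30, f_da=5, f_aa=0)
    B.classify_species([b])
    assert b.stoichiometry == 1.0
    assert b.species_class == "donor-only"
    assert B.select_and_sort([b]) == []


def test_species_misclassification_rate_below_5_percent():
    cfg = ds.two_state_config(seed=11, duration=200.0)  # 75% doubly, 15% D-only, 10% A-only
    stream = ds.simulate_bursts(cfg)
    trace = B.estimate_background(B.bin_photons(stream, 1e-3))
    found = B.find_bursts(trace)
    by_class = B.sort_species(found, CorrectionSet())
    sel = by_class["doubly"]
    t = stream.truth
    # match selected bursts to truth intervals and count non-doubly intruders
    wrong = total = 0
    starts, stops = t.start.to_numpy(), t.stop.to_numpy()
    kinds = t.kind.to_numpy()
    for b in sel:
        t0, t1 = b.start_bin * 1e-3, (b.end_bin + 1) * 1e-3
        overlap = np.flatnonzero((starts < t1) & (stops > t0))
        if overlap.size != 1:
            continue  # ambiguous (overlapping transits): not a classification test case
        total += 1
        if kinds[overlap[0]] != "doubly-labeled":
            wrong += 1
    assert total > 300
    assert wrong / total < 0.05
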