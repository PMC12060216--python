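"""Preprocessing chain: OD conversion, motion handling, filtering, MBLL."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirstates as ns
from nirstates import optics
from nirstates.design import Event
from nirstates.preprocess import ODSeries, apply_bandpass

FS = 20.0


def _od(arr, events=()):
    return ODSeries(arr, FS, events=list(events))


# ---------------------------------------------------------------------------
# intensity -> OD


def test_constant_intensity_gives_zero_od():
    raw = ns.RawRecording(np.full((2, 3, 100), 2.5), FS)
    od = ns.intensity_to_od(raw)
    assert np.allclose(od.od, 0.0)


def test_od_single_dip_matches_formula():
    """I = I0 e^-1 at one sample -> od = 1 up to the mean-reference offset."""
    I = np.full((2, 1, 200), 1.0)
    I[:, :, 50] = np.exp(-1.0)
    od = ns.intensity_to_od(ns.RawRecording(I, FS))
    offset = -np.log(I[0, 0].mean())  # ln(mean/I0)
    assert np.allclose(od.od[:, :, 50], 1.0 - offset, atol=1e-12)


def test_od_scale_invariance():
    rng = np.random.default_rng(0)
    I = np.exp(rng.normal(0, 0.01, (2, 4, 300)))
    od1 = ns.intensity_to_od(ns.RawRecording(I, FS)).od
    od2 = ns.intensity_to_od(ns.RawRecording(2.0 * I, FS)).od
    assert np.allclose(od1, od2, atol=1e-12)


def test_nonpositive_intensity_names_channel():
    I = np.ones((2, 3, 50))
    I[1, 2, 10] = 0.0
    with pytest.raises(ValueError, match="channel 3"):
        ns.intensity_to_od(ns.RawRecording(I, FS))


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(0.1, 10.0))
def test_od_scale_invariance_property(scale):
    rng = np.random.default_rng(1)
    I = np.exp(rng.normal(0, 0.02, (1, 2, 100)))
    base = ns.intensity_to_od(ns.RawRecording(I, FS, wavelengths=(690.0,))).od
    scaled = ns.intensity_to_od(
        ns.RawRecording(scale * I, FS, wavelengths=(690.0,))
    ).od
    assert np.allclose(base, scaled, atol=1e-10)


# ---------------------------------------------------------------------------
# motion artifacts


def test_clean_signal_not_flagged():
    t = np.arange(2000) / FS
    x = 0.01 * np.sin(2 * np.pi * 0.05 * t)
    mask = ns.detect_motion_artifacts(_od(np.tile(x, (2, 3, 1))))
    assert not mask.any()


def test_zero_signal_not_flagged():
    mask = ns.detect_motion_artifacts(_od(np.zeros((2, 2, 500))))
    assert not mask.any()


def test_step_artifact_flagged_near_transition():
    x = np.zeros((2, 1, 2000))
    x[:, :, 1000:] = 0.5
    mask = ns.detect_motion_artifacts(_od(x), amp_thresh=0.2)
    assert mask[0, 995:1005].all()
    assert not mask[0, :900].any() and not mask[0, 1100:].any()


def test_spline_correct_noop_on_empty_mask():
    rng = np.random.default_rng(2)
    x = 0.005 * rng.standard_normal((2, 2, 1000))
    od = _od(x)
    out = ns.spline_correct(od, np.zeros((2, 1000), dtype=bool))
    assert np.array_equal(out.od, x)


def test_baseline_shift_corrected_to_under_ten_percent():
    """A 0.3 OD step is re-leveled to < 0.03 OD residual."""
    rng = np.random.default_rng(3)
    x = 0.003 * rng.standard_normal((2, 1, 4000))
    x[:, :, 2000:] += 0.3
    od = _od(x)
    mask = ns.detect_motion_artifacts(od)
    assert mask.any()
    out = ns.spline_correct(od, mask)
    resid = out.od[0, 0, 2200:2600].mean() - out.od[0, 0, 1400:1800].mean()
    assert abs(resid) < 0.03


def test_spline_correction_roughly_idempotent():
    rng = np.random.default_rng(4)
    x = 0.003 * rng.standard_normal((2, 1, 4000))
    x[:, :, 2000:] += 0.3
    od = _od(x)
    mask = ns.detect_motion_artifacts(od)
    once = ns.spline_correct(od, mask)
    twice = ns.spline_correct(once, mask)
    assert np.abs(twice.od - once.od).max() < 0.02


# ---------------------------------------------------------------------------
# band-pass


def test_filter_passband_and_stopband():
    t = np.arange(0, 200, 1 / FS)
    slow = np.sin(2 * np.pi * 0.05 * t)
    fast = np.sin(2 * np.pi * 1.1 * t)
    out_slow = apply_bandpass(slow, FS, 0.0, 0.1)
    out_fast = apply_bandpass(fast, FS, 0.0, 0.1)
    mid = slice(500, -500)  # avoid edges
    assert out_slow[mid].std() > 0.95 * slow[mid].std()
    assert out_fast[mid].std() < 0.1 * fast[mid].std()


def test_dc_preserved_by_lowpass():
    x = np.full(2000, 3.7)
    assert np.allclose(apply_bandpass(x, FS, 0.0, 0.1), 3.7, atol=1e-9)


def test_bad_band_edges_rejected():
    x = _od(np.zeros((2, 1, 100)))
    with pytest.raises(ValueError, match="below Nyquist"):
        ns.bandpass(x, 0.0, 11.0)
    with pytest.raises(ValueError, match="below high"):
        ns.bandpass(x, 0.2, 0.1)


# ---------------------------------------------------------------------------
# MBLL inversion


def test_zero_od_gives_zero_concentration():
    conc = ns.od_to_concentration(_od(np.zeros((2, 5, 100))))
    assert np.allclose(conc.oxy, 0) and np.allclose(conc.deoxy, 0)
    assert np.allclose(conc.total, 0)


def test_forward_inverse_round_trip_exact():
    rng = np.random.default_rng(5)
    oxy = rng.normal(0, 1, (4, 300))
    deoxy = rng.normal(0, 0.3, (4, 300))
    A = optics.mbll_matrix()
    od = optics.concentration_to_od(oxy, deoxy, A)
    conc = ns.od_to_concentration(_od(od))
    assert np.allclose(conc.oxy, oxy, atol=1e-9)
    assert np.allclose(conc.deoxy, deoxy, atol=1e-9)


def test_doubling_dpf_halves_concentration():
    rng = np.random.default_rng(6)
    od = _od(rng.normal(0, 0.01, (2, 3, 100)))
    c1 = ns.od_to_concentration(od, dpf=(6.0, 6.0))
    c2 = ns.od_to_concentration(od, dpf=(12.0, 12.0))
    assert np.allclose(c2.oxy, c1.oxy / 2, atol=1e-12)


def test_singular_extinction_rejected():
    with pytest.raises(ValueError, match="singular"):
        ns.od_to_concentration(
            _od(np.zeros((2, 1, 10))), extinction=np.ones((2, 2))
        )


def test_total_equals_oxy_plus_deoxy_through_chain(default_subject):
    rec, _ = default_subject
    conc = ns.preprocess_recording(rec)
    assert np.allclose(conc.total, conc.oxy + conc.deoxy, atol=1e-9)


# ---------------------------------------------------------------------------
# block averaging


def _conc_with_events(oxy, events):
    return ns.ConcentrationSeries(
        oxy, -oxy / 3, FS, events=list(events)
    )


def test_identical_trials_average_to_single_trial():
    n = int(150 * FS)
    oxy = np.zeros((2, n))
    events = [Event(10.0, 5.0, "A"), Event(60.0, 5.0, "A")]
    for ev in events:
        a = int(ev.onset * FS)
        oxy[:, a : a + int(5 * FS)] = 1.0
    ba = ns.block_average(_conc_with_events(oxy, events), window=(-5.0, 20.0))
    a = int(10.0 * FS)
    single = oxy[:, a - 100 : a + 400 + 1]
    assert np.allclose(ba.traces["A"], single, atol=1e-12)
    assert ba.n_trials["A"] == 2


def test_opposite_trials_cancel():
    n = int(150 * FS)
    oxy = np.zeros((1, n))
    events = [Event(10.0, 5.0, "A"), Event(60.0, 5.0, "A")]
    oxy[:, 200 : 200 + 100] = 1.0
    oxy[:, 1200 : 1200 + 100] = -1.0
    ba = ns.block_average(_conc_with_events(oxy, events), window=(-5.0, 20.0))
    assert np.allclose(ba.traces["A"], 0.0, atol=1e-12)


def test_out_of_bounds_trials_dropped_with_warning():
    n = int(100 * FS)
    oxy = np.zeros((1, n))
    events = [Event(10.0, 5.0, "A"), Event(95.0, 5.0, "A")]
    with pytest.warns(UserWarning, match="dropping"):
        ba = ns.block_average(_conc_with_events(oxy, events), window=(-5.0, 85.0))
    assert ba.n_trials["A"] == 1


def test_all_trials_out_of_bounds_errors():
    oxy = np.zeros((1, int(20 * FS)))
    with pytest.raises(ValueError, match="outside the record"):
        ns.block_average(
            _conc_with_events(oxy, [Event(10.0, 5.0, "A")]), window=(-5.0, 85.0)
        )


def test_noiseless_block_average_peak_equals_response_peak(
    clean_params, design
):
    """With a single unit response and no noise the block average attains the
    response peak (regressors are unit-peak normalised)."""
    rec, truth = ns.simulate_subject(clean_params, design, "HC", seed=3)
    conc = ns.preprocess_recording(rec, correct_motion=False, band=(0.0, 9.0))
    ba = ns.block_average(conc, design.block_events(), window=(-5.0, 85.0))
    ch = 27  # channel 28, SMA, true beta 0.8 in both conditions
    for cond in design.conditions:
        assert ba.traces[cond][ch].max() == pytest.approx(
            truth.true_beta[ch, 0], rel=0.02
        )


# ---------------------------------------------------------------------------
# chain properties


def test_chain_linearity_without_motion_correction(clean_params, design):
    """Preprocessing (motion correction off) is linear: the chain applied to
    the sum of two signals equals the sum of the chained signals."""
    from dataclasses import replace

    p1 = clean_params
    beta2 = {g: 0.5 * b for g, b in ns.default_true_beta().items()}
    p2 = replace(clean_params, true_beta=beta2)
    r1, _ = ns.simulate_subject(p1, design, "HC", seed=5)
    r2, _ = ns.simulate_subject(p2, design, "HC", seed=5)
    od1 = ns.intensity_to_od(r1).od
    od2 = ns.intensity_to_od(r2).od
    summed = ns.RawRecording(np.exp(-(od1 + od2)), FS, events=r1.events)

    def chain(rec):
        oxy = ns.preprocess_recording(rec, correct_motion=False).oxy
        # mean-referencing of OD makes the chain affine; compare the linear part
        return oxy - oxy.mean(axis=1, keepdims=True)

    assert np.allclose(chain(summed), chain(r1) + chain(r2), atol=1e-9)
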