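"""Preprocessing chain for continuous-wave fNIRS recordings.

The chain mirrors the standard Homer-style pipeline for block-design oxy-Hb
analysis:

1. light intensity -> optical density (negative natural log around the
   channel's temporal mean),
2. channel-wise motion-artifact detection (sliding-window amplitude and
   variance criteria) and smoothing-spline correction with segment
   re-leveling,
3. zero-phase low-pass/band-pass filtering (default pass band 0.0-0.1 Hz),
4. optical density -> chromophore concentration change via the modified
   Beer-Lambert law,
5. per-condition block averaging over a -5..+85 s peristimulus window.

All stages are linear except the artifact correction, and every output
carries a provenance list recording the parameters applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from . import optics
from .design import Event


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawRecording:
    """Per-channel, per-wavelength light-intensity time series.

    ``intensity`` has shape (n_wavelengths, n_channels, n_samples) in
    arbitrary units and must be strictly positive.
    """

    intensity: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float] = optics.WAVELENGTHS
    events: list[Event] = field(default_factory=list)
    subject: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[0] != len(self.wavelengths):
            raise ValueError(
                "intensity must be (n_wavelengths, n_channels, n_samples)"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.intensity.shape[2] / self.sampling_rate
        for ev in self.events:
            if ev.onset < 0 or ev.onset + ev.duration > dur + 1e-9:
                raise ValueError(f"event {ev} outside record of {dur:.1f} s")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass
class ODSeries:
    """Optical density, shape (n_wavelengths, n_channels, n_samples)."""

    od: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float] = optics.WAVELENGTHS
    events: list[Event] = field(default_factory=list)
    subject: str = ""
    group: str = ""
    provenance: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density contains non-finite values")


@dataclass
class ConcentrationSeries:
    """Hemoglobin concentration change, µM, shape (n_channels, n_samples).

    ``total`` is always ``oxy + deoxy``.
    """

    oxy: np.ndarray
    deoxy: np.ndarray
    sampling_rate: float
    events: list[Event] = field(default_factory=list)
    subject: str = ""
    group: str = ""
    dpf: tuple[float, float] = optics.DEFAULT_DPF
    separation_cm: float = optics.DEFAULT_SEPARATION_CM
    provenance: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.shape != self.deoxy.shape or self.oxy.ndim != 2:
            raise ValueError("oxy/deoxy must be matching (n_channels, n_samples) arrays")

    @property
    def total(self) -> np.ndarray:
        return self.oxy + self.deoxy

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[0]

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]


@dataclass
class BlockAverage:
    """Trial-averaged peristimulus oxy-Hb traces per condition.

    ``traces[condition]`` is (n_channels, n_window_samples) covering
    ``window`` seconds around each event onset, each trial baseline-
    referenced to its own prestimulus mean.
    """

    traces: dict[str, np.ndarray]
    n_trials: dict[str, int]
    window: tuple[float, float]
    sampling_rate: float

    def time_axis(self) -> np.ndarray:
        lo, hi = self.window
        n = int(round((hi - lo) * self.sampling_rate)) + 1
        return lo + np.arange(n) / self.sampling_rate


# ---------------------------------------------------------------------------
# operations


def intensity_to_od(raw: RawRecording) -> ODSeries:
    """Convert light intensity to optical density.

    od(c, λ, t) = -ln( I(c, λ, t) / mean_t I(c, λ, ·) ), the Homer
    convention (natural log, referenced to the channel's temporal mean), so
    a stationary signal has zero-mean OD.
    """
    I = raw.intensity
    if np.any(I <= 0):
        w, c, _ = np.unravel_index(int(np.argmax(I <= 0)), I.shape)
        raise ValueError(
            f"nonpositive intensity at channel {c + 1}, wavelength {raw.wavelengths[w]:g} nm"
        )
    od = -np.log(I / I.mean(axis=2, keepdims=True))
    return ODSeries(
        od,
        raw.sampling_rate,
        raw.wavelengths,
        list(raw.events),
        raw.subject,
        raw.group,
        provenance=[("intensity_to_od", "mean-referenced natural log")],
    )


def detect_motion_artifacts(
    od: ODSeries,
    amp_thresh: float = 0.2,
    std_thresh: float = 50.0,
    window: float = 0.5,
    mask_extend: float = 1.0,
) -> np.ndarray:
    """Channel-wise motion-artifact mask.

    A sample is flagged when the peak-to-peak OD excursion inside the
    sliding window around it exceeds ``amp_thresh`` (absolute, OD units) or
    ``std_thresh`` times the channel's sample-to-sample standard deviation.
    Flagged samples are extended by ``mask_extend`` seconds on each side so
    the artifact's tails are included in the corrected segment.  A channel
    is flagged if either wavelength trips a criterion; the mask has shape
    (n_channels, n_samples).
    """
    if amp_thresh <= 0 or std_thresh <= 0:
        raise ValueError("thresholds must be positive")
    win = int(round(window * od.sampling_rate))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    x = od.od
    ptp = maximum_filter1d(x, win, axis=2, mode="nearest") - minimum_filter1d(
        x, win, axis=2, mode="nearest"
    )
    # robust scale of the innovation process per channel/wavelength
    dstd = np.diff(x, axis=2).std(axis=2, keepdims=True)
    flagged = (ptp > amp_thresh) | (ptp > std_thresh * np.maximum(dstd, 1e-15))
    mask = flagged.any(axis=0)
    ext = int(round(mask_extend * od.sampling_rate))
    if ext > 0 and mask.any():
        mask = maximum_filter1d(mask.astype(np.uint8), 2 * ext + 1, axis=1) > 0
    return mask


def _segments(mask_1d: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of a boolean vector as (start, stop, flagged)."""
    out = []
    edges = np.flatnonzero(np.diff(mask_1d.astype(int))) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [mask_1d.size]])
    for a, b in zip(starts, stops):
        out.append((int(a), int(b), bool(mask_1d[a])))
    return out


def spline_correct(od: ODSeries, mask: np.ndarray, p: float = 0.99) -> ODSeries:
    """Smoothing-spline motion correction with segment re-leveling.

    Within each flagged segment a smoothing spline (MATLAB ``csaps``-style
    parameter ``p``; 1 = interpolating, 0 = linear) is fitted and
    subtracted, removing the slow artifact waveform.  The series is then
    rebuilt segment by segment, shifting each segment so adjacent levels
    connect — this removes baseline steps while leaving the internal shape
    of clean segments untouched.
    """
    if not (0 < p <= 1):
        raise ValueError("smoothing parameter p must be in (0, 1]")
    x = od.od.copy()
    n = x.shape[2]
    fs = od.sampling_rate
    edge = max(2, int(round(2.0 * fs)))  # samples used for level matching
    lam = (1.0 - p) / p  # csaps p -> smoothing-spline penalty weight
    t_all = np.arange(n) / fs
    for c in range(x.shape[1]):
        if not mask[c].any():
            continue
        segs = _segments(mask[c])
        if len(segs) == 1 and segs[0][2]:
            warnings.warn(
                f"channel {c + 1}: artifact mask spans the whole record; de-trending only"
            )
        for w in range(x.shape[0]):
            pieces = []
            for a, b, flagged in segs:
                seg = x[w, c, a:b].copy()
                if flagged and b - a >= 5:
                    spl = make_smoothing_spline(t_all[a:b], seg, lam=lam if lam > 0 else None)
                    seg = seg - spl(t_all[a:b])
                elif flagged:
                    seg = seg - seg.mean()
                pieces.append(seg)
            # re-level: shift every segment to connect with its predecessor
            rebuilt = pieces[0]
            for seg in pieces[1:]:
                k = min(edge, rebuilt.size, seg.size)
                offset = rebuilt[-k:].mean() - seg[:k].mean()
                rebuilt = np.concatenate([rebuilt, seg + offset])
            x[w, c] = rebuilt
    return replace(
        od,
        od=x,
        provenance=od.provenance + [("spline_correct", {"p": p})],
    )


def _butter_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({nyq} Hz)")
    if low >= high:
        raise ValueError("low cutoff must be below high cutoff")
    if low <= 0:
        return sp_signal.butter(order, high / nyq, btype="low", output="sos")
    return sp_signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")


def apply_bandpass(
    x: np.ndarray, fs: float, low: float = 0.0, high: float = 0.1, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth filter along the last axis.

    A 0 Hz low edge degenerates to a pure low-pass, so DC is preserved.
    Forward-backward application keeps event timing unshifted.  Exposed
    separately so GLM task regressors can be filtered identically to the
    data.
    """
    sos = _butter_sos(low, high, fs, order)
    return sp_signal.sosfiltfilt(sos, x, axis=-1)


def bandpass(od: ODSeries, low: float = 0.0, high: float = 0.1, order: int = 4) -> ODSeries:
    """Filter optical density to the hemodynamic band (default 0.0-0.1 Hz)."""
    filtered = apply_bandpass(od.od, od.sampling_rate, low, high, order)
    return replace(
        od,
        od=filtered,
        provenance=od.provenance + [("bandpass", {"low": low, "high": high, "order": order})],
    )


def od_to_concentration(
    od: ODSeries,
    dpf: tuple[float, float] = optics.DEFAULT_DPF,
    separation_cm: float = optics.DEFAULT_SEPARATION_CM,
    extinction: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Invert the modified Beer-Lambert law per channel and sample.

    Solves the 2x2 system Δc = (L·DPF·E)^-1 · od for HbO and HbR (µM);
    total Hb is their sum by construction.
    """
    A = optics.mbll_matrix(dpf, separation_cm, extinction)
    oxy, deoxy = optics.od_to_concentration_pair(od.od, A)
    return ConcentrationSeries(
        oxy,
        deoxy,
        od.sampling_rate,
        list(od.events),
        od.subject,
        od.group,
        dpf=dpf,
        separation_cm=separation_cm,
        provenance=od.provenance
        + [("od_to_concentration", {"dpf": dpf, "separation_cm": separation_cm})],
    )


def block_average(
    conc: ConcentrationSeries,
    events: list[Event] | None = None,
    window: tuple[float, float] = (-5.0, 85.0),
) -> BlockAverage:
    """Average oxy-Hb peristimulus windows per condition.

    Each trial is baseline-referenced to its own prestimulus (window start
    to 0 s) mean; trials whose window exceeds the record bounds are dropped
    with a warning.
    """
    events = conc.events if events is None else events
    if not events:
        raise ValueError("no events to average")
    fs = conc.sampling_rate
    lo, hi = window
    n_win = int(round((hi - lo) * fs)) + 1
    n_base = max(1, int(round(-lo * fs)))
    traces: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cond in dict.fromkeys(ev.condition for ev in events):
        trials = []
        for ev in events:
            if ev.condition != cond:
                continue
            a = int(round((ev.onset + lo) * fs))
            if a < 0 or a + n_win > conc.n_samples:
                warnings.warn(
                    f"dropping {cond} trial at {ev.onset:.1f} s: window exceeds record"
                )
                continue
            seg = conc.oxy[:, a : a + n_win]
            trials.append(seg - seg[:, :n_base].mean(axis=1, keepdims=True))
        if not trials:
            raise ValueError(f"all {cond} trials fall outside the record")
        traces[cond] = np.mean(trials, axis=0)
        counts[cond] = len(trials)
    return BlockAverage(traces, counts, window, fs)


def preprocess_recording(
    raw: RawRecording,
    amp_thresh: float = 0.2,
    std_thresh: float = 50.0,
    motion_window: float = 0.5,
    spline_p: float = 0.99,
    band: tuple[float, float] = (0.0, 0.1),
    dpf: tuple[float, float] = optics.DEFAULT_DPF,
    separation_cm: float = optics.DEFAULT_SEPARATION_CM,
    correct_motion: bool = True,
) -> ConcentrationSeries:
    """Run the full chain: OD, motion correction, filter, concentration."""
    od = intensity_to_od(raw)
    if correct_motion:
        mask = detect_motion_artifacts(od, amp_thresh, std_thresh, motion_window)
        if mask.any():
            od = spline_correct(od, mask, spline_p)
    od = bandpass(od, *band)
    return od_to_concentration(od, dpf, separation_cm)
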