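"""Synthetic fNIRS cohort generator with known ground truth.

Emulates the acquisition of the imagined-walking study — 53 channels at
20 Hz, dual 690/830 nm wavelengths, two 60 s motor-imagery blocks (with and
without rhythmic auditory cueing) flanked by 30 s rests — for three groups:
Parkinson's patients with freezing of gait (PD+FOG), without (PD-FOG), and
healthy controls (HC).

Each subject's oxy-Hb signal is the sum of

* task responses: per-condition amplitude β times the unit-peak canonical
  HRF regressor (identical construction to the GLM module, so noiseless
  recovery is exact),
* a region-level latent process switching between connectivity regimes
  along a hidden first-order Markov chain (equicorrelated regions, AR(1)
  temporal smoothing) — the ground truth for the dynamic-connectivity
  stage,
* physiological oscillations (Mayer waves ~0.1 Hz, respiration ~0.3 Hz,
  cardiac ~1.1 Hz), linear drift and white measurement noise.

Deoxy-Hb is -1/3 of the structured oxy-Hb signal plus independent noise
(the typical anticorrelation; downstream analyses use oxy-Hb only).  The
concentrations are pushed through the forward modified Beer-Lambert law and
exponentiated around a baseline intensity; motion artifacts (spikes and
baseline steps, OD units) are injected last.  Identical seeds give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import optics
from .design import TaskDesign
from .glm import HRFParams, condition_regressor
from .montage import ChannelMontage, default_montage, roi_channels
from .preprocess import RawRecording

GROUPS = ("PD+FOG", "PD-FOG", "HC")


def default_true_beta(
    montage: ChannelMontage | None = None,
    conditions: tuple[str, ...] = ("MI", "MI+RAS"),
) -> dict[str, np.ndarray]:
    """Group-specific activation maps (channels x conditions, µM).

    Motor regions (SMA, M1) respond at 0.8 µM in controls and non-freezers
    under both conditions.  Freezers activate the same regions at only
    0.25 µM during plain motor imagery and are restored to 0.8 µM when the
    auditory rhythm is added — the qualitative activation pattern the
    package's group statistics are meant to detect.  Non-motor regions
    carry no task response.
    """
    montage = montage or default_montage()
    n_ch = len(montage.channels)
    active = sorted(roi_channels(montage, "SMA") + roi_channels(montage, "M1"))
    idx = [c - 1 for c in active]
    maps: dict[str, np.ndarray] = {}
    for g in GROUPS:
        b = np.zeros((n_ch, len(conditions)))
        for j, cond in enumerate(conditions):
            if g == "PD+FOG" and cond == "MI":
                b[idx, j] = 0.25
            else:
                b[idx, j] = 0.8
        maps[g] = b
    return maps


def equicorrelation(n: int, r: float) -> np.ndarray:
    """n x n correlation matrix with constant off-diagonal r (PSD for r in [0,1))."""
    if not -1.0 / (n - 1) < r < 1.0:
        raise ValueError(f"equicorrelation {r} not positive definite for n={n}")
    return (1.0 - r) * np.eye(n) + r * np.ones((n, n))


def default_state_correlations(region_labels: list[str]) -> list[np.ndarray]:
    """Correlation matrices of the three default connectivity regimes.

    Brain connectivity states differ in topography as well as overall
    strength: the low-strength state is uncoupled (r = 0), the
    medium-strength state couples the sensorimotor circuit (SMA, M1, S1)
    at r = 0.9 with a mild anticorrelation (r = -0.3) between the motor
    and non-motor networks (the classic task-positive/task-negative
    opposition), and the high-strength state is globally coupled
    (uniform r = 0.9).  Mean strength is strictly increasing across the
    three, so ordering states by centroid strength recovers the generating
    order, and the patterns are mutually well separated relative to the
    sampling noise of 30 s windowed correlations in the 0-0.1 Hz band.
    """
    n = len(region_labels)
    motor = [
        i
        for i, r in enumerate(region_labels)
        if any(m in r for m in ("SMA", "M1", "S1"))
    ]
    nonmotor = [i for i in range(n) if i not in motor]
    low = np.eye(n)
    med = np.eye(n)
    for i in motor:
        for j in motor:
            if i != j:
                med[i, j] = 0.9
    for i in motor:
        for j in nonmotor:
            med[i, j] = med[j, i] = -0.3
    high = equicorrelation(n, 0.9)
    # guard: block substitution must stay positive definite
    for C in (low, med, high):
        np.linalg.cholesky(C)
    return [low, med, high]


def uniform_transition_matrix(n_states: int) -> np.ndarray:
    """Row-stochastic matrix with equal off-diagonal mass (diagonal set later
    from the mean dwell time)."""
    P = np.full((n_states, n_states), 1.0 / n_states)
    return P


@dataclass
class SimulationParams:
    """All knobs of the generator, with study-scale defaults.

    Noise amplitudes are in µM of oxy-Hb; artifact amplitudes in OD units.
    The three connectivity regimes are equicorrelated region processes at
    The three connectivity regimes default to the topographically distinct
    low / medium / high strength patterns of
    :func:`default_state_correlations`, switching with a 150 s mean dwell.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"PD+FOG": 21, "PD-FOG": 24, "HC": 10}
    )
    true_beta: dict[str, np.ndarray] | None = None  # filled from montage if None
    beta_subject_sd: float = 0.3      # between-subject scatter of active-channel β, µM
    hrf: HRFParams = field(default_factory=HRFParams)
    # physiological noise
    drift_slope: float = 0.1          # µM over the full session, random sign
    mayer_amp: float = 0.08           # µM
    mayer_freq: float = 0.1           # Hz
    resp_amp: float = 0.05
    resp_freq: float = 0.3
    cardiac_amp: float = 0.1
    cardiac_freq: float = 1.1
    white_sd: float = 0.3             # µM per sample
    # region-level latent connectivity process
    latent_sd: float = 0.1            # µM
    latent_tau: float = 1.0           # AR(1) time constant, s
    hemispheric_nodes: bool = True    # latent lives on L/R region nodes
    state_correlations: list | None = None  # correlation matrices; defaults per region set
    transition: np.ndarray | None = None  # off-diagonal structure; uniform if None
    mean_dwell: float = 150.0         # s
    # motion artifacts (OD units)
    spike_rate_per_min: float = 0.2
    spike_amp_od: float = 0.3
    spike_width_s: tuple[float, float] = (0.5, 2.0)
    shift_rate_per_session: float = 0.2
    shift_amp_od: float = 0.3
    # optics
    baseline_intensity: float = 1.0
    dpf: tuple[float, float] = optics.DEFAULT_DPF
    separation_cm: float = optics.DEFAULT_SEPARATION_CM
    seed: int = 0

    @property
    def n_states(self) -> int:
        return 3 if self.state_correlations is None else len(self.state_correlations)

    def validate(self, n_regions: int) -> None:
        for name in (
            "white_sd",
            "latent_sd",
            "mayer_amp",
            "resp_amp",
            "cardiac_amp",
            "spike_rate_per_min",
            "shift_rate_per_session",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline intensity must be positive")
        if self.state_correlations is not None:
            for C in self.state_correlations:
                C = np.asarray(C, dtype=float)
                if C.shape != (n_regions, n_regions) or not np.allclose(C, C.T):
                    raise ValueError("state correlation matrices must be symmetric n_regions^2")
                if np.linalg.eigvalsh(C).min() < -1e-10:
                    raise ValueError("state correlation matrix not positive semi-definite")
        if self.transition is not None:
            P = np.asarray(self.transition, dtype=float)
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("transition-matrix rows must sum to 1")

    def state_covariances(self, region_labels: list[str]) -> list[np.ndarray]:
        mats = (
            default_state_correlations(region_labels)
            if self.state_correlations is None
            else [np.asarray(C, dtype=float) for C in self.state_correlations]
        )
        return [self.latent_sd**2 * C for C in mats]


@dataclass
class SyntheticGroundTruth:
    """Hidden parameters behind one simulated recording."""

    true_beta: np.ndarray          # channels x conditions, µM
    state_sequence: np.ndarray     # per-sample hidden state id
    state_covariances: list[np.ndarray]
    artifact_times: list[float]    # s
    latent: np.ndarray             # regions x time, µM
    region_labels: list[str]
    conditions: tuple[str, ...]


def sample_state_sequence(
    markov: np.ndarray,
    length: int,
    seed: int | np.random.Generator,
    dwell: float | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """First-order Markov state sequence.

    ``markov`` must be row-stochastic.  If ``dwell`` (seconds, with ``dt``
    the step) is given, the diagonal is replaced by ``1 - dt/dwell`` and the
    off-diagonal mass rescaled to match, turning ``markov`` into the
    conditional jump distribution.
    """
    P = np.asarray(markov, dtype=float).copy()
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < -1e-12):
        raise ValueError("transition probabilities must be nonnegative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("transition-matrix rows must sum to 1")
    n = P.shape[0]
    if dwell is not None:
        if dwell <= dt:
            raise ValueError("mean dwell must exceed the time step")
        p_stay = 1.0 - dt / dwell
        Q = P.copy()
        np.fill_diagonal(Q, 0.0)
        rows = Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Q = np.where(rows > 0, Q / rows, np.full_like(Q, 1.0 / max(n - 1, 1)))
        if n > 1:
            np.fill_diagonal(Q, 0.0)
        P = p_stay * np.eye(n) + (1.0 - p_stay) * Q
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdf = np.cumsum(P, axis=1)
    seq = np.empty(length, dtype=np.int64)
    u = rng.random(length)
    state = int(rng.integers(n))
    for t in range(length):
        seq[t] = state
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, n - 1)
    return seq


def _latent_process(
    cov_chols: list[np.ndarray],
    state_seq: np.ndarray,
    tau: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """AR(1)-smoothed, state-switching correlated region process.

    Innovations are drawn from the covariance of the state active at each
    sample; AR smoothing keeps the spectrum inside the hemodynamic band.
    Returned with unit marginal variance scaling (the Cholesky factors carry
    the amplitude).
    """
    n = state_seq.size
    k = cov_chols[0].shape[0]
    phi = np.exp(-dt / tau)
    scale = np.sqrt(1.0 - phi**2)
    z = rng.standard_normal((n, k))
    # innovation per sample under its state's covariance
    e = np.empty_like(z)
    for s, L in enumerate(cov_chols):
        idx = state_seq == s
        if idx.any():
            e[idx] = z[idx] @ L.T
    x = np.empty_like(e)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + scale * e[t]
    return x.T  # regions x time


def simulate_subject(
    params: SimulationParams,
    design: TaskDesign,
    group: str,
    seed: int,
    montage: ChannelMontage | None = None,
    subject: str = "",
) -> tuple[RawRecording, SyntheticGroundTruth]:
    """Generate one subject's dual-wavelength recording plus its ground truth."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    montage = montage or default_montage()
    regions = montage.node_labels(hemispheric=params.hemispheric_nodes)
    params.validate(len(regions))
    rng = np.random.default_rng(seed)

    fs = design.sampling_rate
    n = design.n_samples
    n_ch = len(montage.channels)
    t = np.arange(n) / fs
    conditions = design.conditions
    events = design.trial_events()

    beta_maps = params.true_beta or default_true_beta(montage, conditions)
    beta = np.asarray(beta_maps[group], dtype=float).copy()
    if beta.shape != (n_ch, len(conditions)):
        raise ValueError("true_beta must be channels x conditions")
    if params.beta_subject_sd > 0:
        # idiosyncratic response amplitudes on the responsive channels; the
        # subject's realised β is the ground truth recovery is judged against
        active = beta != 0
        beta[active] += params.beta_subject_sd * rng.standard_normal(int(active.sum()))

    # task response, via the same unit-peak regressor the GLM fits
    regs = np.column_stack(
        [condition_regressor(events, c, n, fs, params.hrf) for c in conditions]
    )
    task = beta @ regs.T  # channels x time

    # hidden connectivity regime and region latent process
    P = (
        np.asarray(params.transition, dtype=float)
        if params.transition is not None
        else uniform_transition_matrix(params.n_states)
    )
    state_seq = sample_state_sequence(P, n, rng, dwell=params.mean_dwell, dt=1.0 / fs)
    covs = params.state_covariances(regions)
    if params.latent_sd > 0:
        chols = [np.linalg.cholesky(C) for C in covs]
        latent = _latent_process(chols, state_seq, params.latent_tau, 1.0 / fs, rng)
    else:
        latent = np.zeros((len(regions), n))
    region_index = np.array(
        [
            regions.index(montage.node_of(ch, params.hemispheric_nodes))
            for ch in montage.channels
        ]
    )
    latent_ch = latent[region_index]  # channels x time

    # physiological noise + drift + white noise
    physio = np.zeros((n_ch, n))
    for amp, freq in (
        (params.mayer_amp, params.mayer_freq),
        (params.resp_amp, params.resp_freq),
        (params.cardiac_amp, params.cardiac_freq),
    ):
        if amp > 0:
            phases = rng.uniform(0, 2 * np.pi, n_ch)
            physio += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    slopes = params.drift_slope * rng.choice([-1.0, 1.0], n_ch)
    drift = slopes[:, None] * (t[None, :] / max(t[-1], 1e-9))
    white = params.white_sd * rng.standard_normal((n_ch, n)) if params.white_sd > 0 else 0.0

    structured = task + latent_ch
    oxy = structured + physio + drift + white
    deoxy_noise = (
        params.white_sd / 3.0 * rng.standard_normal((n_ch, n)) if params.white_sd > 0 else 0.0
    )
    deoxy = -structured / 3.0 + deoxy_noise

    # forward modified Beer-Lambert and exponentiation around baseline
    A = optics.mbll_matrix(params.dpf, params.separation_cm)
    od = optics.concentration_to_od(oxy, deoxy, A)

    # motion artifacts: global events, random channel subsets, OD units
    artifact_times: list[float] = []
    dur_min = n / fs / 60.0
    n_spikes = rng.poisson(params.spike_rate_per_min * dur_min)
    for _ in range(n_spikes):
        t0 = rng.uniform(5.0, n / fs - 5.0)
        width = rng.uniform(*params.spike_width_s)
        amp = params.spike_amp_od * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        affected = rng.random(n_ch) < 0.5
        # width is the full (±3 sigma) extent of the bump
        bump = amp * np.exp(-0.5 * ((t - t0) / (width / 6.0)) ** 2)
        od[:, affected, :] += bump[None, None, :]
        artifact_times.append(t0)
    n_shifts = rng.poisson(params.shift_rate_per_session)
    for _ in range(n_shifts):
        t0 = rng.uniform(5.0, n / fs - 5.0)
        amp = params.shift_amp_od * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        affected = rng.random(n_ch) < 0.5
        od[:, affected, int(round(t0 * fs)) :] += amp
        artifact_times.append(t0)

    intensity = params.baseline_intensity * np.exp(-od)
    raw = RawRecording(
        intensity,
        fs,
        optics.WAVELENGTHS,
        events=list(events),
        subject=subject or f"{group}-s{seed}",
        group=group,
    )
    truth = SyntheticGroundTruth(
        true_beta=beta.copy(),
        state_sequence=state_seq,
        state_covariances=covs,
        artifact_times=sorted(artifact_times),
        latent=latent,
        region_labels=list(regions),
        conditions=tuple(conditions),
    )
    return raw, truth


def simulate_cohort(
    params: SimulationParams,
    design: TaskDesign,
    montage: ChannelMontage | None = None,
) -> list[tuple[RawRecording, SyntheticGroundTruth]]:
    """Simulate every subject of the three groups.

    Per-subject seeds are spawned deterministically from ``params.seed``;
    changing the master seed changes every subject.
    """
    for g, n in params.n_subjects.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects for group statistics")
    montage = montage or default_montage()
    ss = np.random.SeedSequence(params.seed)
    total = sum(params.n_subjects.values())
    children = ss.generate_state(total)
    out = []
    i = 0
    for g in GROUPS:
        if g not in params.n_subjects:
            continue
        for j in range(params.n_subjects[g]):
            seed = int(children[i] % (2**31 - 1))
            i += 1
            rec, truth = simulate_subject(
                params, design, g, seed, montage, subject=f"{g}-{j + 1:02d}"
            )
            out.append((rec, truth))
    return out
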