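"""Sliding-window dynamic functional connectivity and k-means state analysis.

Region-averaged oxy-Hb series are correlated inside a sliding window
(default 50 s, 1 s step); the vectorised upper-triangular correlation of
every window, pooled over all subjects and both task conditions, is
clustered with k-means.  The number of states K is chosen by the elbow
criterion — the K maximising the perpendicular distance of the
within-cluster sum-of-squares curve from the chord joining its endpoints —
and states are relabelled by ascending mean connectivity strength (low /
medium / high for K = 3).  Per-subject state dynamics are summarised by
occurrence probabilities and the K x K transition-percentage matrix over
consecutive window pairs (self-transitions included; entry (x, y) is the
percentage of transitions from state x to state y, and the whole matrix
sums to 100).

:class:`ConnectivityStateModel` / :class:`StateResults` follow the
model-fit-results idiom; module-level functions expose each step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .group_stats import paired_ttest_roi
from .montage import ChannelMontage
from .preprocess import ConcentrationSeries
from scipy import stats as sp_stats


def region_series(
    conc: ConcentrationSeries, montage: ChannelMontage, hemispheric: bool = True
) -> pd.DataFrame:
    """Average oxy-Hb over each node's channels -> (nodes x time) frame.

    With ``hemispheric`` (default) the nodes are the per-hemisphere region
    labels (``L-SMA``, ``R-SMA``, ...); otherwise the plain regions.
    """
    rows = {}
    for node, chans in montage.node_channels(hemispheric).items():
        idx = [ch - 1 for ch in chans]
        rows[node] = conc.oxy[idx].mean(axis=0)
    return pd.DataFrame(rows).T


@dataclass
class DFCWindowSet:
    """Vectorised windowed correlations, possibly pooled over subjects.

    ``windows`` is (n_windows, n_pairs): the upper triangle of each
    window's node-correlation matrix.  ``subjects`` and ``conditions`` give
    each window's provenance.
    """

    windows: np.ndarray
    node_labels: list[str]
    window_s: float
    step_s: float
    sampling_rate: float
    subjects: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    conditions: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    groups: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    start_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def pair_labels(self) -> list[str]:
        return [
            f"{a}~{b}" for a, b in itertools.combinations(self.node_labels, 2)
        ]

    def mean_strength(self) -> np.ndarray:
        return self.windows.mean(axis=1)


def _window_correlations(x: np.ndarray, win: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations of (nodes x time) in sliding windows.

    Returns (n_windows x n_pairs upper-triangle matrix, start sample of
    each window).  Constant series within a window give correlation 0.
    """
    n_nodes, T = x.shape
    n_win = (T - win) // step + 1
    iu = np.triu_indices(n_nodes, k=1)
    out = np.empty((n_win, iu[0].size))
    starts = np.arange(n_win) * step
    for i, a in enumerate(starts):
        seg = x[:, a : a + win]
        seg = seg - seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1)
        bad = sd == 0
        denom = np.outer(sd, sd)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (seg @ seg.T) / win / np.where(denom == 0, np.nan, denom)
        C[bad, :] = 0.0
        C[:, bad] = 0.0
        out[i] = np.clip(C[iu], -1.0, 1.0)
    return out, starts


def sliding_window_fc(
    node_ts: pd.DataFrame | np.ndarray,
    sampling_rate: float,
    window_s: float = 50.0,
    step_s: float = 1.0,
    node_labels: list[str] | None = None,
    subject: str = "",
    condition: str = "",
    group: str = "",
    fisher_z: bool = False,
) -> DFCWindowSet:
    """Windowed correlation vectors for one subject's node series.

    ``fisher_z`` optionally maps correlations through atanh before
    clustering; the default keeps raw correlation space so that centroid
    "strength" reads directly as mean correlation.
    """
    if isinstance(node_ts, pd.DataFrame):
        node_labels = list(node_ts.index)
        x = node_ts.to_numpy(dtype=float)
    else:
        x = np.asarray(node_ts, dtype=float)
        node_labels = node_labels or [f"node{i + 1}" for i in range(x.shape[0])]
    win = int(round(window_s * sampling_rate))
    step = int(round(step_s * sampling_rate))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if step < 1:
        raise ValueError("step must be at least 1 sample")
    if x.shape[1] < win:
        raise ValueError("series shorter than one window")
    W, starts = _window_correlations(x, win, step)
    if fisher_z:
        W = np.arctanh(np.clip(W, -0.999999, 0.999999))
    n = W.shape[0]
    return DFCWindowSet(
        W,
        node_labels,
        window_s,
        step_s,
        sampling_rate,
        subjects=np.array([subject] * n, dtype=object),
        conditions=np.array([condition] * n, dtype=object),
        groups=np.array([group] * n, dtype=object),
        start_samples=starts,
    )


def pool_windows(sets: list[DFCWindowSet]) -> DFCWindowSet:
    """Concatenate window sets (shared state space across subjects/conditions)."""
    first = sets[0]
    for s in sets[1:]:
        if s.node_labels != first.node_labels:
            raise ValueError("window sets have different node labels")
    return DFCWindowSet(
        np.vstack([s.windows for s in sets]),
        first.node_labels,
        first.window_s,
        first.step_s,
        first.sampling_rate,
        subjects=np.concatenate([s.subjects for s in sets]),
        conditions=np.concatenate([s.conditions for s in sets]),
        groups=np.concatenate([s.groups for s in sets]),
        start_samples=np.concatenate([s.start_samples for s in sets]),
    )


def exemplar_indices(windows: DFCWindowSet, order: int = 3) -> np.ndarray:
    """Indices of exemplar windows: local maxima of across-pair FC variance.

    With heavily overlapping windows, consecutive correlation vectors are
    nearly identical and windows spanning a state transition trace dense
    bridges between states.  Following standard dynamic-connectivity
    practice, a sparse set of exemplars — windows at local maxima of the
    variance of the correlation vector, per subject/condition series — is
    used to estimate the cluster-number curve.  ``order`` is the
    neighbourhood half-width (in windows) of the local-maximum test.
    """
    from scipy.signal import argrelextrema

    subj = windows.subjects
    cond = windows.conditions
    out: list[int] = []
    for key in dict.fromkeys(zip(subj, cond)):
        idx = np.flatnonzero((subj == key[0]) & (cond == key[1]))
        if idx.size < 2 * order + 1:
            out.extend(idx)
            continue
        v = windows.windows[idx].var(axis=1)
        loc = argrelextrema(v, np.greater, order=order)[0]
        out.extend(idx[loc])
    return np.asarray(sorted(out), dtype=int)


def wcss_curve(
    windows: DFCWindowSet,
    k_range: range,
    seed: int,
    n_init: int = 10,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Within-cluster sum of squares W(k) over the candidate K values."""
    X = windows.windows if subset is None else windows.windows[subset]
    out = np.empty(len(k_range))
    for i, k in enumerate(k_range):
        if k > X.shape[0]:
            raise ValueError(f"k={k} exceeds the number of windows ({X.shape[0]})")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        out[i] = km.inertia_
    return out


def choose_k_elbow(
    windows: DFCWindowSet,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_init: int = 30,
    exemplars: bool = True,
) -> int:
    """Elbow selection of the number of connectivity states.

    The chord joins (k_min, W(k_min)) to (k_max, W(k_max)); the selected K
    maximises the perpendicular distance from (k, W(k)) to that chord, ties
    broken toward the smallest k.  By default W(k) is computed on the
    exemplar windows (see :func:`exemplar_indices`); set ``exemplars=False``
    to use every window.
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("elbow needs at least 3 candidate K values")
    subset = None
    if exemplars:
        ex = exemplar_indices(windows)
        if ex.size > max(ks) * 3:
            subset = ex
    W = wcss_curve(windows, k_range, seed, n_init, subset=subset)
    # scale both axes to the chord's span so the distance is well conditioned
    x = np.asarray(ks, dtype=float)
    x = (x - x[0]) / (x[-1] - x[0])
    span = W[0] - W[-1]
    y = (W - W[-1]) / (span if span != 0 else 1.0)
    # chord from (0, 1) to (1, 0): distance ∝ |x + y - 1|, elbow lies below
    d = -(x + y - 1.0) / np.sqrt(2.0)
    best = int(np.argmax(np.round(d, 12)))  # first index wins exact ties
    return ks[best]


def choose_k_crossval(
    windows: DFCWindowSet,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[int, list[int]]:
    """Subject-level cross-validated K selection.

    Subjects are split into ``n_folds`` folds; the elbow criterion is
    re-run on the windows of each fold's complement.  Returns the modal K
    and the per-fold choices — a stable state count reproduces across every
    fold.
    """
    subjects = list(dict.fromkeys(windows.subjects))
    if len(subjects) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds = np.array_split(order, n_folds)
    per_fold = []
    for fold in folds:
        held = {subjects[i] for i in fold}
        keep = ~np.isin(windows.subjects, list(held))
        sub = DFCWindowSet(
            windows.windows[keep],
            windows.node_labels,
            windows.window_s,
            windows.step_s,
            windows.sampling_rate,
            subjects=windows.subjects[keep],
            conditions=windows.conditions[keep],
            groups=windows.groups[keep],
            start_samples=windows.start_samples[keep],
        )
        per_fold.append(choose_k_elbow(sub, k_range, seed=seed))
    vals, counts = np.unique(per_fold, return_counts=True)
    return int(vals[np.argmax(counts)]), [int(k) for k in per_fold]


def occurrence_probability(labels: np.ndarray, n_states: int) -> np.ndarray:
    """Fraction of windows in each state; sums to 1."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("no windows for this subject")
    return np.bincount(lab, minlength=n_states) / lab.size


def transition_percentage(labels: np.ndarray, n_states: int) -> np.ndarray:
    """K x K transition matrix in percent of all consecutive-window pairs.

    Entry (x, y) is the percentage of transitions from state x to state y,
    self-transitions included; the whole matrix sums to 100.
    """
    lab = np.asarray(labels)
    if lab.size < 2:
        raise ValueError("need at least 2 windows to count transitions")
    M = np.zeros((n_states, n_states))
    np.add.at(M, (lab[:-1], lab[1:]), 1.0)
    return 100.0 * M / (lab.size - 1)


@dataclass
class StateResults:
    """Fitted connectivity-state decomposition.

    States are ordered by ascending centroid mean connectivity (state 0 =
    lowest strength).  ``occurrence`` and ``transitions`` are per-subject
    (and per condition where available) summaries.
    """

    n_states: int
    centroids: np.ndarray            # K x n_pairs, ordered low -> high strength
    labels: np.ndarray               # per pooled window
    windows: DFCWindowSet
    seed: int
    inertia: float
    state_names: list[str]

    @property
    def centroid_strength(self) -> np.ndarray:
        return self.centroids.mean(axis=1)

    def state_matrix(self, state: int) -> np.ndarray:
        """Centroid as a full symmetric node x node correlation matrix."""
        n = self.windows.n_nodes
        M = np.eye(n)
        iu = np.triu_indices(n, k=1)
        M[iu] = self.centroids[state]
        M[(iu[1], iu[0])] = self.centroids[state]
        return M

    def _subject_masks(self) -> dict[tuple[str, str], np.ndarray]:
        keys = {}
        subj = self.windows.subjects
        cond = self.windows.conditions
        for s, c in dict.fromkeys(zip(subj, cond)):
            keys[(s, c)] = (subj == s) & (cond == c)
        return keys

    def occurrence_table(self) -> pd.DataFrame:
        rows = []
        for (s, c), m in self._subject_masks().items():
            occ = occurrence_probability(self.labels[m], self.n_states)
            g = self.windows.groups[m][0] if m.any() else ""
            row = {"subject": s, "condition": c, "group": g}
            row.update({f"occ_{name}": v for name, v in zip(self.state_names, occ)})
            rows.append(row)
        return pd.DataFrame(rows)

    def transition_table(self) -> pd.DataFrame:
        rows = []
        for (s, c), m in self._subject_masks().items():
            tr = transition_percentage(self.labels[m], self.n_states)
            g = self.windows.groups[m][0] if m.any() else ""
            row = {"subject": s, "condition": c, "group": g}
            for i, a in enumerate(self.state_names):
                for j, b in enumerate(self.state_names):
                    row[f"trans_{a}->{b}"] = tr[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    def subject_occurrence(self, subject: str, condition: str | None = None) -> np.ndarray:
        m = self.windows.subjects == subject
        if condition is not None:
            m &= self.windows.conditions == condition
        if not m.any():
            raise KeyError(f"unknown subject {subject!r}")
        return occurrence_probability(self.labels[m], self.n_states)

    def subject_transitions(self, subject: str, condition: str | None = None) -> np.ndarray:
        m = self.windows.subjects == subject
        if condition is not None:
            m &= self.windows.conditions == condition
        if not m.any():
            raise KeyError(f"unknown subject {subject!r}")
        return transition_percentage(self.labels[m], self.n_states)

    def summary(self) -> str:
        occ = self.occurrence_table()
        lines = [
            f"Connectivity-state model: K={self.n_states} "
            f"({', '.join(self.state_names)})",
            f"  window {self.windows.window_s:g} s, step {self.windows.step_s:g} s,"
            f" {self.windows.windows.shape[0]} windows,"
            f" nodes: {', '.join(self.windows.node_labels)}",
            f"  centroid mean strength: "
            + ", ".join(f"{v:.3f}" for v in self.centroid_strength),
            f"  pooled occurrence: "
            + ", ".join(
                f"{name}={occ[f'occ_{name}'].mean():.3f}" for name in self.state_names
            ),
        ]
        return "\n".join(lines)


_STATE_NAMES3 = ["low", "medium", "high"]


class ConnectivityStateModel:
    """K-means decomposition of pooled windowed-connectivity vectors.

    Parameters
    ----------
    windows : DFCWindowSet
        Pooled over subjects and conditions (one shared state space).
    k : int or None
        Number of states; when None it is chosen by the elbow criterion
        over ``k_range`` at fit time.
    """

    def __init__(
        self,
        windows: DFCWindowSet,
        k: int | None = None,
        k_range: range = range(2, 11),
        n_init: int = 50,
    ):
        self.windows = windows
        self.k = k
        self.k_range = k_range
        self.n_init = n_init

    def fit(self, seed: int = 0) -> StateResults:
        k = self.k if self.k is not None else choose_k_elbow(
            self.windows, self.k_range, seed=seed
        )
        if k < 2:
            raise ValueError("need at least 2 states")
        X = self.windows.windows
        if k > X.shape[0]:
            raise ValueError(f"K={k} exceeds window count {X.shape[0]}")
        km = KMeans(n_clusters=k, n_init=self.n_init, random_state=seed).fit(X)
        order = np.argsort(km.cluster_centers_.mean(axis=1))
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        names = (
            list(_STATE_NAMES3)
            if k == 3
            else [f"state{i + 1}" for i in range(k)]
        )
        return StateResults(
            n_states=k,
            centroids=km.cluster_centers_[order],
            labels=remap[km.labels_],
            windows=self.windows,
            seed=seed,
            inertia=float(km.inertia_),
            state_names=names,
        )


def cluster_states(
    windows: DFCWindowSet, k: int, seed: int = 0, n_init: int = 50
) -> StateResults:
    """Functional wrapper around :class:`ConnectivityStateModel`."""
    return ConnectivityStateModel(windows, k=k, n_init=n_init).fit(seed)


def compare_state_dynamics(results: StateResults, alpha: float = 0.05) -> pd.DataFrame:
    """Group and condition comparisons of occurrence/transition features.

    Between groups (within each condition): two-sample pooled t.  Within
    groups (between conditions, paired by subject): paired t.  Returns a
    tidy table of feature, contrast, statistic and p.
    """
    occ = results.occurrence_table()
    tr = results.transition_table()
    feats = occ.merge(tr, on=["subject", "condition", "group"])
    return compare_dynamics_features(feats, alpha)


def compare_dynamics_features(feats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the dynamics comparisons on a per-subject feature table.

    ``feats`` needs ``subject``, ``condition``, ``group`` columns plus any
    number of ``occ_*`` / ``trans_*`` feature columns.
    """
    feature_cols = [c for c in feats.columns if c.startswith(("occ_", "trans_"))]
    conditions = list(dict.fromkeys(feats["condition"]))
    groups = list(dict.fromkeys(feats["group"]))
    rows = []
    for cond in conditions:
        sub = feats[feats["condition"] == cond]
        for ga, gb in itertools.combinations(groups, 2):
            a = sub[sub["group"] == ga]
            b = sub[sub["group"] == gb]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"groups {ga!r}/{gb!r} need n >= 2")
            for f in feature_cols:
                t, p = sp_stats.ttest_ind(a[f], b[f])
                rows.append(
                    {
                        "feature": f,
                        "contrast": f"{ga} vs {gb}",
                        "condition": cond,
                        "t": float(t),
                        "p": float(p),
                        "significant": bool(p < alpha),
                    }
                )
    if len(conditions) == 2:
        c1, c2 = conditions
        for g in groups:
            a = feats[(feats["group"] == g) & (feats["condition"] == c1)].set_index("subject")
            b = feats[(feats["group"] == g) & (feats["condition"] == c2)].set_index("subject")
            common = a.index.intersection(b.index)
            if len(common) < 2:
                continue
            for f in feature_cols:
                t, p, _ = paired_ttest_roi(
                    a.loc[common, f].to_numpy(), b.loc[common, f].to_numpy()
                )
                rows.append(
                    {
                        "feature": f,
                        "contrast": f"{g}: {c1} vs {c2}",
                        "condition": "paired",
                        "t": t,
                        "p": p,
                        "significant": bool(p < alpha) if np.isfinite(p) else False,
                    }
                )
    return pd.DataFrame(rows)
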