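"""Sliding-window connectivity, elbow K selection, state statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import nirstates as ns
from nirstates.dynamic_fc import DFCWindowSet, compare_dynamics_features

FS = 20.0


def _windows_from_array(X, **kw):
    n_pairs = X.shape[1]
    n_nodes = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    defaults = dict(
        node_labels=[f"n{i}" for i in range(n_nodes)],
        window_s=30.0,
        step_s=1.0,
        sampling_rate=FS,
        subjects=np.array(["s"] * len(X), dtype=object),
        conditions=np.array([""] * len(X), dtype=object),
        groups=np.array([""] * len(X), dtype=object),
        start_samples=np.arange(len(X)),
    )
    defaults.update(kw)
    return DFCWindowSet(X, **defaults)


# ---------------------------------------------------------------------------
# sliding-window correlations


def test_identical_series_fully_correlated():
    x = np.vstack([np.sin(np.arange(400) / 10)] * 2)
    ws = ns.sliding_window_fc(x, FS, window_s=5.0, step_s=1.0)
    assert np.allclose(ws.windows, 1.0)


def test_window_count_formula():
    x = np.random.default_rng(0).normal(size=(3, 100))
    ws = ns.sliding_window_fc(x, 1.0, window_s=20.0, step_s=10.0)
    assert ws.windows.shape[0] == (100 - 20) // 10 + 1 == 9


def test_independent_noise_correlations_shrink_with_window():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 40000))
    ws = ns.sliding_window_fc(x, 1.0, window_s=2000.0, step_s=2000.0)
    assert np.abs(ws.windows).max() < 4 / np.sqrt(2000)


def test_constant_series_flagged_as_zero():
    x = np.vstack([np.ones(200), np.random.default_rng(2).normal(size=200)])
    ws = ns.sliding_window_fc(x, FS, window_s=5.0, step_s=5.0)
    assert np.allclose(ws.windows, 0.0)


def test_window_shorter_than_two_samples_rejected():
    x = np.zeros((2, 100))
    with pytest.raises(ValueError):
        ns.sliding_window_fc(x, FS, window_s=0.01)


# ---------------------------------------------------------------------------
# elbow


def _gaussian_blob_windows(seed, centers, n_per=60, sd=0.05):
    rng = np.random.default_rng(seed)
    X = np.vstack([c + sd * rng.standard_normal((n_per, len(c))) for c in centers])
    return _windows_from_array(np.clip(X, -1, 1))


def test_elbow_finds_three_separated_clusters():
    centers = [np.full(10, v) for v in (0.0, 0.45, 0.9)]
    ws = _gaussian_blob_windows(0, centers)
    assert ns.choose_k_elbow(ws, range(2, 11), seed=0, exemplars=False) == 3


def test_elbow_tie_breaks_to_smallest_k(monkeypatch):
    """Perfectly linear W(k) has zero distance everywhere -> smallest k."""
    import nirstates.dynamic_fc as dfc

    ws = _gaussian_blob_windows(1, [np.zeros(10)])
    monkeypatch.setattr(dfc, "wcss_curve", lambda *a, **k: np.linspace(100.0, 20.0, 9))
    assert dfc.choose_k_elbow(ws, range(2, 11), seed=0) == 2


def test_single_degenerate_cluster_gives_k_min():
    """All windows identical: W(k) is flat (zero) so the elbow degenerates
    to the smallest candidate K."""
    ws = _gaussian_blob_windows(2, [np.full(10, 0.3)], n_per=100, sd=0.0)
    assert ns.choose_k_elbow(ws, range(2, 11), seed=0, exemplars=False) == 2


def test_short_k_range_rejected():
    ws = _gaussian_blob_windows(3, [np.zeros(10)])
    with pytest.raises(ValueError, match="3 candidate"):
        ns.choose_k_elbow(ws, range(2, 4), seed=0)


# ---------------------------------------------------------------------------
# k-means states


def test_known_regimes_recovered_with_high_ari():
    centers = [np.full(10, v) for v in (0.0, 0.45, 0.9)]
    ws = _gaussian_blob_windows(4, centers, n_per=80)
    truth = np.repeat([0, 1, 2], 80)
    res = ns.cluster_states(ws, 3, seed=0)
    assert adjusted_rand_score(truth, res.labels) > 0.9
    assert list(res.state_names) == ["low", "medium", "high"]
    # strength ordering strictly increasing
    assert np.all(np.diff(res.centroid_strength) > 0)


def test_duplication_invariance():
    centers = [np.full(6, v) for v in (0.1, 0.8)]
    ws = _gaussian_blob_windows(5, centers, n_per=40)
    dup = _windows_from_array(np.vstack([ws.windows, ws.windows]))
    r1 = ns.cluster_states(ws, 2, seed=1)
    r2 = ns.cluster_states(dup, 2, seed=1)
    assert np.allclose(r1.centroids, r2.centroids, atol=1e-8)
    assert np.array_equal(r2.labels[: len(ws.windows)], r1.labels)


def test_same_seed_same_model():
    centers = [np.full(6, v) for v in (0.1, 0.5, 0.9)]
    ws = _gaussian_blob_windows(6, centers)
    r1 = ns.cluster_states(ws, 3, seed=7)
    r2 = ns.cluster_states(ws, 3, seed=7)
    assert np.array_equal(r1.labels, r2.labels)
    assert np.allclose(r1.centroids, r2.centroids)


def test_k_larger_than_windows_rejected():
    ws = _windows_from_array(np.zeros((3, 6)))
    with pytest.raises(ValueError):
        ns.cluster_states(ws, 5, seed=0)


def test_kmeans_objective_matches_exhaustive_search_k2():
    """Brute-force oracle: on 10 windows in 3 dimensions the k-means solution
    attains the optimum over all 2-cluster assignments."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 3))
    ws = _windows_from_array(np.clip(X, -1, 1) * 0.5)
    res = ns.cluster_states(ws, 2, seed=0, n_init=50)

    def wcss(assign):
        tot = 0.0
        for lab in (0, 1):
            pts = ws.windows[np.array(assign) == lab]
            if len(pts):
                tot += ((pts - pts.mean(axis=0)) ** 2).sum()
        return tot

    best = min(
        wcss(bits)
        for bits in itertools.product([0, 1], repeat=10)
        if 0 < sum(bits) < 10
    )
    assert res.inertia == pytest.approx(best, rel=1e-9)


# ---------------------------------------------------------------------------
# occurrence and transitions


def test_occurrence_all_one_state():
    assert np.allclose(
        ns.occurrence_probability(np.zeros(9, dtype=int), 3), [1, 0, 0]
    )


def test_occurrence_counts():
    occ = ns.occurrence_probability(np.array([0, 0, 1, 2]), 3)
    assert np.allclose(occ, [0.5, 0.25, 0.25])


def test_occurrence_empty_rejected():
    with pytest.raises(ValueError):
        ns.occurrence_probability(np.array([], dtype=int), 3)


def test_transition_constant_labels_on_diagonal():
    tr = ns.transition_percentage(np.ones(10, dtype=int), 3)
    assert tr[1, 1] == 100.0 and tr.sum() == pytest.approx(100.0)


def test_transition_alternating_labels():
    tr = ns.transition_percentage(np.array([0, 1, 0, 1, 0]), 2)
    assert tr[0, 1] == 50.0 and tr[1, 0] == 50.0


def test_transition_single_window_rejected():
    with pytest.raises(ValueError):
        ns.transition_percentage(np.array([1]), 3)


def test_markov_chain_statistics_recovered_at_scale():
    """Occurrence and transition percentages converge to the generating chain."""
    P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
    seq = ns.sample_state_sequence(P, 10_000, seed=0)
    occ = ns.occurrence_probability(seq, 3)
    # stationary distribution of P
    w, v = np.linalg.eig(P.T)
    stat = np.real(v[:, np.argmax(np.real(w))])
    stat = stat / stat.sum()
    assert np.abs(occ - stat).max() < 0.05
    tr = ns.transition_percentage(seq, 3) / 100.0
    # conditional transition probabilities within 4 sigma binomial error
    cond = tr / tr.sum(axis=1, keepdims=True)
    n_from = np.bincount(seq[:-1], minlength=3)[:, None]
    tol = 4 * np.sqrt(P * (1 - P) / n_from)
    assert np.all(np.abs(cond - P) < tol + 1e-12)


@settings(deadline=None, max_examples=30)
@given(labels=st.lists(st.integers(0, 2), min_size=2, max_size=60))
def test_dynamics_sum_invariants(labels):
    lab = np.array(labels)
    occ = ns.occurrence_probability(lab, 3)
    tr = ns.transition_percentage(lab, 3)
    assert occ.sum() == pytest.approx(1.0)
    assert tr.sum() == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# group dynamics comparisons


def _feature_frame(rng, n_per_group=10, shift=0.0):
    rows = []
    for g in ("A", "B", "C"):
        for i in range(n_per_group):
            for cond in ("MI", "MI+RAS"):
                mu = shift if (g == "A" and cond == "MI") else 0.0
                rows.append(
                    {
                        "subject": f"{g}{i}",
                        "condition": cond,
                        "group": g,
                        "occ_low": mu + rng.normal(),
                        "trans_low->high": rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


def test_constructed_group_effect_flagged():
    rng = np.random.default_rng(8)
    out = compare_dynamics_features(_feature_frame(rng, 15, shift=3.0))
    hit = out[
        (out["feature"] == "occ_low")
        & (out["condition"] == "MI")
        & (out["contrast"].str.startswith("A vs"))
    ]
    assert hit["significant"].all()


def test_identical_groups_mostly_nonsignificant():
    rng = np.random.default_rng(9)
    out = compare_dynamics_features(_feature_frame(rng, 12))
    assert out["significant"].mean() < 0.25


def test_small_group_rejected_in_comparisons():
    rng = np.random.default_rng(10)
    df = _feature_frame(rng, 2)
    df = df[~((df["group"] == "B") & (df["subject"] == "B1"))]
    with pytest.raises(ValueError, match="n >= 2"):
        compare_dynamics_features(df)


def test_state_results_tables_satisfy_invariants(design, montage):
    """Occurrence rows sum to 1 and transition rows to 100 for every
    subject/condition of a small simulated run."""
    params = ns.SimulationParams(seed=5, n_subjects={"PD+FOG": 2, "PD-FOG": 2, "HC": 2})
    cohort = ns.simulate_cohort(params, design)
    sets = []
    for rec, _ in cohort:
        conc = ns.preprocess_recording(rec)
        resid = ns.ActivationModel.from_preprocessed(conc).task_residual()
        nodes = ns.region_series(resid, montage)
        for cond in design.conditions:
            a = int((design.block_onset(cond) - 25) * FS)
            b = int((design.block_onset(cond) + 85) * FS)
            sets.append(
                ns.sliding_window_fc(
                    nodes.iloc[:, max(a, 0) : b],
                    FS,
                    subject=rec.subject,
                    condition=cond,
                    group=rec.group,
                )
            )
    pooled = ns.pool_windows(sets)
    res = ns.cluster_states(pooled, 3, seed=0, n_init=10)
    occ = res.occurrence_table()
    occ_cols = [c for c in occ.columns if c.startswith("occ_")]
    assert np.allclose(occ[occ_cols].sum(axis=1), 1.0)
    tr = res.transition_table()
    tr_cols = [c for c in tr.columns if c.startswith("trans_")]
    assert np.allclose(tr[tr_cols].sum(axis=1), 100.0)
    with pytest.raises(KeyError):
        res.subject_occurrence("nobody")


def test_crossval_k_is_unanimous_on_separated_clusters():
    """Subject-level 5-fold refits agree on K for well-separated states."""
    rng = np.random.default_rng(11)
    X, subj = [], []
    for s in range(10):
        for c in (0.0, 0.45, 0.9):
            X.append(c + 0.05 * rng.standard_normal((20, 10)))
            subj.extend([f"s{s}"] * 20)
    ws = _windows_from_array(
        np.clip(np.vstack(X), -1, 1),
        subjects=np.array(subj, dtype=object),
        conditions=np.array([""] * len(subj), dtype=object),
        groups=np.array([""] * len(subj), dtype=object),
        start_samples=np.arange(len(subj)),
    )
    K, per_fold = ns.choose_k_crossval(ws, seed=0)
    assert K == 3
    assert per_fold == [3, 3, 3, 3, 3]


def test_crossval_needs_enough_subjects():
    ws = _windows_from_array(np.zeros((10, 6)))
    with pytest.raises(ValueError, match="subjects"):
        ns.choose_k_crossval(ws, n_folds=5)
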