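"""End-to-end study pipeline: simulate -> preprocess -> GLM -> group
statistics -> dynamic connectivity states -> graph metrics -> report.

All randomness flows from the single seed in :class:`StudyConfig`; every
stage writes its intermediate tables to the output directory so the report
is fully traceable, and rerunning with the same config reproduces it
byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphmetrics
from .design import TaskDesign
from .dynamic_fc import (
    ConnectivityStateModel,
    compare_state_dynamics,
    pool_windows,
    region_series,
    sliding_window_fc,
)
from .glm import ActivationModel
from .group_stats import (
    anova_across_groups,
    lsd_posthoc,
    one_sample_activation,
    paired_ttest_roi,
    select_rois,
)
from .montage import default_montage
from .preprocess import preprocess_recording
from .simulate import GROUPS, SimulationParams, simulate_cohort

log = logging.getLogger("nirstates")


@dataclass
class StudyConfig:
    """Every parameter of a full study run."""

    seed: int = 0
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"PD+FOG": 21, "PD-FOG": 24, "HC": 10}
    )
    alpha: float = 0.05
    drift_order: int = 1
    band: tuple[float, float] = (0.0, 0.1)
    window_s: float = 50.0
    step_s: float = 1.0
    k: int | None = None           # None -> elbow selection
    k_range: tuple[int, int] = (2, 10)
    n_init: int = 50
    correct_motion: bool = True
    regress_task: bool = True      # remove evoked responses before connectivity
    out_dir: str = "study_out"
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in obj:
            obj["band"] = tuple(obj["band"])
        if "k_range" in obj:
            obj["k_range"] = tuple(obj["k_range"])
        return cls(**obj)

    def simulation_params(self) -> SimulationParams:
        return replace(
            SimulationParams(seed=self.seed, n_subjects=dict(self.n_subjects)),
            **self.sim_overrides,
        )


@dataclass
class StudyReport:
    """All result tables of one run plus the provenance block."""

    betas: pd.DataFrame
    activation: dict[tuple[str, str], pd.DataFrame]
    anova: dict[str, pd.DataFrame]
    rois: list[int]
    posthoc: pd.DataFrame
    paired: pd.DataFrame
    state_summary: dict
    occurrence: pd.DataFrame
    transitions: pd.DataFrame
    dynamics: pd.DataFrame
    state_metrics: list[dict]
    provenance: dict


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config, design, montage):
    return simulate_cohort(config.simulation_params(), design, montage)


@_stage("preprocess")
def _preprocess(config, cohort):
    return [
        preprocess_recording(rec, band=config.band, correct_motion=config.correct_motion)
        for rec, _ in cohort
    ]


@_stage("glm")
def _glm(config, concs):
    frames = []
    for conc in concs:
        res = ActivationModel.from_preprocessed(conc, drift_order=config.drift_order).fit()
        frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


def _beta_matrix(betas: pd.DataFrame, group: str, condition: str) -> np.ndarray:
    sub = betas[(betas["group"] == group) & (betas["condition"] == condition)]
    return (
        sub.pivot(index="subject", columns="channel", values="beta")
        .sort_index(axis=1)
        .to_numpy()
    )


@_stage("stats")
def _group_stats(config, betas):
    conditions = list(dict.fromkeys(betas["condition"]))
    groups = [g for g in GROUPS if g in set(betas["group"])]
    activation = {
        (g, c): one_sample_activation(_beta_matrix(betas, g, c), config.alpha)
        for g in groups
        for c in conditions
    }
    anova = {
        c: anova_across_groups(
            {g: _beta_matrix(betas, g, c) for g in groups}, fdr=True, alpha=config.alpha
        )
        for c in conditions
    }
    # ROI selection follows the no-cueing contrast (first condition)
    rois = select_rois(anova[conditions[0]])
    posthoc_frames = [
        lsd_posthoc({g: _beta_matrix(betas, g, conditions[0]) for g in groups}, ch)
        for ch in rois
    ]
    posthoc = (
        pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames else pd.DataFrame()
    )
    paired_rows = []
    if len(conditions) == 2:
        for ch in rois:
            for g in groups:
                a = _beta_matrix(betas, g, conditions[0])[:, ch - 1]
                b = _beta_matrix(betas, g, conditions[1])[:, ch - 1]
                t, p, md = paired_ttest_roi(a, b)
                paired_rows.append(
                    {"channel": ch, "group": g, "t": t, "p": p, "mean_diff": md}
                )
    paired = pd.DataFrame(paired_rows)
    return activation, anova, rois, posthoc, paired


@_stage("dfc")
def _dfc(config, concs, cohort, design, montage):
    sets = []
    for conc, (rec, _) in zip(concs, cohort):
        if config.regress_task:
            conc = ActivationModel.from_preprocessed(
                conc, drift_order=config.drift_order
            ).task_residual()
        nodes = region_series(conc, montage)
        fs = conc.sampling_rate
        for cond in design.conditions:
            onset = design.block_onset(cond)
            a = int(round((onset - config.window_s / 2) * fs))
            b = int(round((onset + design.task_duration + config.window_s / 2) * fs))
            a, bnd = max(a, 0), min(b, nodes.shape[1])
            seg = nodes.iloc[:, a:bnd]
            sets.append(
                sliding_window_fc(
                    seg,
                    fs,
                    config.window_s,
                    config.step_s,
                    subject=rec.subject,
                    condition=cond,
                    group=rec.group,
                )
            )
    pooled = pool_windows(sets)
    model = ConnectivityStateModel(
        pooled,
        k=config.k,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        n_init=config.n_init,
    )
    return model.fit(seed=config.seed)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline and write every intermediate to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = TaskDesign()
    montage = default_montage()

    cohort = _simulate(config, design, montage)
    concs = _preprocess(config, cohort)
    betas = _glm(config, concs)
    betas.to_csv(out / "betas.csv", index=False)

    activation, anova, rois, posthoc, paired = _group_stats(config, betas)
    for (g, c), tbl in activation.items():
        tbl.to_csv(out / f"activation_{g.replace('+', 'p')}_{c.replace('+', 'p')}.csv",
                   index=False)
    for c, tbl in anova.items():
        tbl.to_csv(out / f"anova_{c.replace('+', 'p')}.csv", index=False)
    posthoc.to_csv(out / "lsd_posthoc.csv", index=False)
    paired.to_csv(out / "roi_paired_t.csv", index=False)

    states = _dfc(config, concs, cohort, design, montage)
    occurrence = states.occurrence_table()
    transitions = states.transition_table()
    occurrence.to_csv(out / "state_occurrence.csv", index=False)
    transitions.to_csv(out / "state_transitions.csv", index=False)
    dynamics = compare_state_dynamics(states, alpha=config.alpha)
    dynamics.to_csv(out / "state_dynamics_tests.csv", index=False)
    metrics = graphmetrics.state_metrics(states.centroids, states.windows.node_labels)

    state_summary = {
        "K": states.n_states,
        "state_names": states.state_names,
        "centroid_strength": states.centroid_strength.tolist(),
        "centroids": states.centroids.tolist(),
        "node_labels": states.windows.node_labels,
        "window_s": config.window_s,
        "step_s": config.step_s,
        "seed": config.seed,
        "metrics": metrics,
    }
    (out / "state_model.json").write_text(json.dumps(state_summary, indent=2))

    provenance = {"config": asdict(config), "n_subjects_total": len(cohort)}
    report = StudyReport(
        betas=betas,
        activation=activation,
        anova=anova,
        rois=rois,
        posthoc=posthoc,
        paired=paired,
        state_summary=state_summary,
        occurrence=occurrence,
        transitions=transitions,
        dynamics=dynamics,
        state_metrics=metrics,
        provenance=provenance,
    )
    (out / "report.json").write_text(
        json.dumps(
            {
                "provenance": provenance,
                "rois": rois,
                "n_states": states.n_states,
                "state_metrics": metrics,
                "significant_dynamics": dynamics[dynamics["significant"]].to_dict("records"),
            },
            indent=2,
            default=str,
        )
    )
    return report
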