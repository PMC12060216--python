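"""Channel-wise GLM activation estimation.

Each channel's oxy-Hb series is regressed on task regressors (per-trial
boxcars convolved with a canonical double-gamma HRF, unit-peak normalised),
polynomial drift terms and a constant.  The per-condition amplitudes β (µM
per unit regressor peak) are the activation measure carried into the group
statistics.

Organised statsmodels-style: :class:`ActivationModel` holds the data and
design; :meth:`ActivationModel.fit` returns :class:`ActivationResults` with
estimates, standard errors, degrees of freedom and a ``summary`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import Event
from .preprocess import ConcentrationSeries, apply_bandpass


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: positive lobe peaking at ``peak_delay`` s,
    undershoot at ``undershoot_delay`` s with relative amplitude
    ``1/undershoot_ratio``."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 6.0
    duration: float = 32.0


def canonical_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the double-gamma HRF at times ``t`` (s), peak normalised to 1."""
    t = np.asarray(t, dtype=float)

    def gpdf(x, a):  # gamma(a, scale=1) density, stable in log space
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp((a - 1) * np.log(np.maximum(x, 1e-300)) - x - gammaln(a))
        return np.where(x > 0, out, 0.0)

    # gamma(a, 1) has its mode at a - 1, so shape = delay + 1 puts the lobe
    # peak exactly at peak_delay
    a1 = params.peak_delay + 1.0
    a2 = params.undershoot_delay + 1.0
    h = gpdf(t, a1) - gpdf(t, a2) / params.undershoot_ratio
    peak = (
        gpdf(np.array([params.peak_delay]), a1)[0]
        - gpdf(np.array([params.peak_delay]), a2)[0] / params.undershoot_ratio
    )
    return h / peak


@dataclass
class DesignMatrix:
    """Time x p regressor matrix with column labels and HRF provenance."""

    X: np.ndarray
    labels: list[str]
    conditions: list[str]
    sampling_rate: float
    hrf: HRFParams = field(default_factory=HRFParams)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # identify the offending columns for the error message
            bad = []
            keep: list[int] = []
            for j in range(self.X.shape[1]):
                trial = keep + [j]
                if np.linalg.matrix_rank(self.X[:, trial]) == len(trial):
                    keep = trial
                else:
                    bad.append(self.labels[j])
            raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")

    @property
    def condition_columns(self) -> dict[str, int]:
        return {c: self.labels.index(c) for c in self.conditions}


def condition_regressor(
    events: list[Event],
    condition: str,
    n_samples: int,
    sampling_rate: float,
    hrf_params: HRFParams = HRFParams(),
) -> np.ndarray:
    """Boxcar-over-trials convolved with the canonical HRF, unit peak.

    Shared with the simulator so that simulated responses and fitted
    regressors are numerically identical.
    """
    box = np.zeros(n_samples)
    found = False
    for ev in events:
        if ev.condition != condition:
            continue
        found = True
        a = int(round(ev.onset * sampling_rate))
        b = int(round((ev.onset + ev.duration) * sampling_rate))
        box[a : min(b, n_samples)] = 1.0
    if not found:
        raise ValueError(f"no events for condition {condition!r}")
    t = np.arange(int(round(hrf_params.duration * sampling_rate)) + 1) / sampling_rate
    h = canonical_hrf(t, hrf_params)
    reg = np.convolve(box, h)[:n_samples] / sampling_rate
    peak = np.abs(reg).max()
    if peak > 0:
        reg = reg / peak
    return reg


def build_design(
    events: list[Event],
    n_samples: int,
    sampling_rate: float,
    hrf_params: HRFParams = HRFParams(),
    drift_order: int = 1,
) -> DesignMatrix:
    """Assemble task regressors + polynomial drift + constant.

    Conditions appear in order of first occurrence in ``events``; drift
    terms are Legendre polynomials on [-1, 1] (orthogonal to the constant).
    """
    conditions = list(dict.fromkeys(ev.condition for ev in events))
    for c in conditions:
        evs = sorted((ev for ev in events if ev.condition == c), key=lambda e: e.onset)
        for e1, e2 in zip(evs, evs[1:]):
            if e1.onset + e1.duration > e2.onset + 1e-9:
                raise ValueError(f"overlapping events in condition {c!r}")
    cols, labels = [], []
    for c in conditions:
        cols.append(condition_regressor(events, c, n_samples, sampling_rate, hrf_params))
        labels.append(c)
    u = np.linspace(-1.0, 1.0, n_samples)
    for d in range(1, drift_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(d)(u))
        labels.append(f"drift{d}")
    cols.append(np.ones(n_samples))
    labels.append("const")
    return DesignMatrix(np.column_stack(cols), labels, conditions, sampling_rate, hrf_params)


@dataclass
class ActivationResults:
    """Per-channel GLM estimates.

    Attributes
    ----------
    beta : (n_channels, n_conditions) array, µM per unit regressor peak.
    se : matching standard errors.
    resid_var : per-channel residual variance.
    dof : residual degrees of freedom (shared across channels).
    """

    beta: np.ndarray
    se: np.ndarray
    resid_var: np.ndarray
    dof: int
    conditions: list[str]
    subject: str = ""
    group: str = ""

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: subject, group, channel, condition, beta, se, dof."""
        rows = []
        for c, ch_beta in enumerate(self.beta, start=1):
            for j, cond in enumerate(self.conditions):
                rows.append(
                    {
                        "subject": self.subject,
                        "group": self.group,
                        "channel": c,
                        "condition": cond,
                        "beta": ch_beta[j],
                        "se": self.se[c - 1, j],
                        "dof": self.dof,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self, top: int = 10) -> str:
        df = self.to_frame()
        df["t"] = df["beta"] / df["se"]
        lines = [
            "Channel-wise GLM activation",
            f"  subject: {self.subject or '-'}  group: {self.group or '-'}",
            f"  conditions: {', '.join(self.conditions)};  residual dof: {self.dof}",
            f"  strongest |t| channels:",
        ]
        best = df.reindex(df["t"].abs().sort_values(ascending=False).index).head(top)
        for _, r in best.iterrows():
            lines.append(
                f"    Ch{int(r.channel):02d} {r.condition:>7s}  beta={r.beta:+.3f} µM"
                f"  se={r.se:.3f}  t={r.t:+.2f}"
            )
        return "\n".join(lines)


class ActivationModel:
    """OLS (optionally AR(1)-prewhitened) GLM for one subject's channels.

    Parameters
    ----------
    conc : ConcentrationSeries
        Preprocessed oxy-Hb series (the model fits oxy-Hb only).
    design : DesignMatrix
        From :func:`build_design`; rows must match the series length.
    """

    def __init__(self, conc: ConcentrationSeries, design: DesignMatrix):
        if design.X.shape[0] != conc.n_samples:
            raise ValueError("design rows must equal number of time points")
        if not np.all(np.isfinite(conc.oxy)):
            raise ValueError("non-finite samples in concentration series")
        self.conc = conc
        self.design = design

    @classmethod
    def from_preprocessed(
        cls,
        conc: ConcentrationSeries,
        hrf_params: HRFParams = HRFParams(),
        drift_order: int = 1,
        match_filter: bool = True,
    ) -> "ActivationModel":
        """Build the design from the series' own events.

        When ``match_filter`` is set and the provenance records a band-pass
        stage, the task regressors are passed through the identical filter,
        so the (linear) filtering cancels from the estimator and noiseless
        responses are recovered exactly.
        """
        design = build_design(
            conc.events, conc.n_samples, conc.sampling_rate, hrf_params, drift_order
        )
        if match_filter:
            for stage, args in conc.provenance:
                if stage == "bandpass":
                    X = design.X.copy()
                    for c in design.conditions:
                        j = design.labels.index(c)
                        X[:, j] = apply_bandpass(
                            X[:, j], conc.sampling_rate, args["low"], args["high"], args["order"]
                        )
                    design = DesignMatrix(
                        X, design.labels, design.conditions, design.sampling_rate, design.hrf
                    )
        return cls(conc, design)

    def fit(self, method: str = "ols") -> ActivationResults:
        """Estimate β per channel.

        ``method='ols'`` is plain least squares; ``method='ar1'`` applies a
        Cochrane-Orcutt AR(1) prewhitening with the lag-1 autocorrelation
        pooled over channels.
        """
        X = self.design.X
        Y = self.conc.oxy.T  # time x channels
        if method == "ar1":
            b0, _ = np.linalg.lstsq(X, Y, rcond=None)[:2]
            R = Y - X @ b0
            num = (R[1:] * R[:-1]).sum()
            den = (R[:-1] ** 2).sum()
            rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
            X = X[1:] - rho * X[:-1]
            Y = Y[1:] - rho * Y[:-1]
        elif method != "ols":
            raise ValueError(f"unknown method {method!r}")
        n, p = X.shape
        dof = n - p
        if dof <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y  # p x channels
        resid = Y - X @ B
        resid_var = (resid**2).sum(axis=0) / dof
        cols = [self.design.labels.index(c) for c in self.design.conditions]
        beta = B[cols].T  # channels x conditions
        se = np.sqrt(np.outer(resid_var, np.diag(XtX_inv)[cols]))
        return ActivationResults(
            beta=beta,
            se=se,
            resid_var=resid_var,
            dof=dof,
            conditions=list(self.design.conditions),
            subject=self.conc.subject,
            group=self.conc.group,
        )


    def task_residual(self) -> ConcentrationSeries:
        """Oxy-Hb with the fitted task and drift components removed.

        Used as the input to connectivity analysis ("background"
        connectivity): when the evoked response is much larger than the
        spontaneous fluctuations it would otherwise dominate every window's
        correlation.  The constant term is retained (correlations ignore
        it); deoxy-Hb is passed through unchanged.
        """
        from dataclasses import replace as _replace

        X = self.design.X
        B = np.linalg.lstsq(X, self.conc.oxy.T, rcond=None)[0]
        keep = [j for j, lab in enumerate(self.design.labels) if lab == "const"]
        drop = [j for j in range(X.shape[1]) if j not in keep]
        fitted = X[:, drop] @ B[drop]
        return _replace(
            self.conc,
            oxy=self.conc.oxy - fitted.T,
            provenance=self.conc.provenance + [("task_residual", {})],
        )


def fit_glm(conc: ConcentrationSeries, design: DesignMatrix) -> ActivationResults:
    """Functional wrapper: OLS fit of ``design`` to each channel."""
    return ActivationModel(conc, design).fit()
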