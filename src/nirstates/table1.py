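"""Recompute demographics-table statistics from printed summaries.

Given a YAML file of per-group summaries (means/SDs/ns, category counts),
emit the statistic column: Pearson chi-square for categorical rows,
one-way ANOVA F for three-group continuous rows, pooled two-sample t for
two-group rows.  Rank-sum rows are marked not computable — the statistic
needs the raw ordinal data, not medians and quartiles.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .group_stats import SummaryStats, anova_from_summary, chi_square_counts, pooled_t_from_summary


def load_summaries(path: str | Path | None = None) -> dict:
    """Load a summaries file; default is the packaged study demographics."""
    if path is None:
        with resources.as_file(
            resources.files("nirstates.data").joinpath("table1_demographics.yaml")
        ) as p:
            text = p.read_text()
    else:
        text = Path(path).read_text()
    try:
        obj = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ValueError(f"malformed summaries file: {e}") from e
    if not isinstance(obj, dict) or not obj:
        raise ValueError("summaries file is empty or not a mapping")
    return obj


def build_table(summaries: dict) -> pd.DataFrame:
    """Statistic table (variable, test, statistic, df, p) from summaries."""
    rows = []
    for var, spec in summaries.items():
        kind = spec.get("test")
        if kind == "chi2":
            counts = np.array(list(spec["counts"].values())).T  # categories x groups
            chi2, df, p = chi_square_counts(counts)
            rows.append({"variable": var, "test": "chi2", "statistic": chi2,
                         "df": str(df), "p": p})
        elif kind == "anova":
            gs = [SummaryStats(**g) for g in spec["groups"].values()]
            F, df1, df2, p = anova_from_summary(gs)
            rows.append({"variable": var, "test": "anova", "statistic": F,
                         "df": f"({df1}, {df2})", "p": p})
        elif kind == "t":
            a, b = (SummaryStats(**g) for g in spec["groups"].values())
            t, df, p = pooled_t_from_summary(a, b)
            rows.append({"variable": var, "test": "t", "statistic": t,
                         "df": str(df), "p": p})
        elif kind == "ranksum":
            rows.append({"variable": var, "test": "ranksum", "statistic": np.nan,
                         "df": "", "p": np.nan,
                         "note": "not computable from summaries"})
        else:
            raise ValueError(f"{var}: unknown test kind {kind!r}")
    df = pd.DataFrame(rows)
    if "note" in df.columns:
        df["note"] = df["note"].fillna("")
    return df
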