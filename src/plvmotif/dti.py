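"""Repeated-measures ANCOVA on per-tract DTI scalars (FA/MD/RD/AD).

The structural arm starts from a long-format table of per-subject,
per-session tract metrics and asks, per (tract, metric), whether groups
differ, whether values change between sessions, and — the question of
interest in a longitudinal design — whether the change differs by group
(group x session interaction), with sex as covariate throughout.

With a complete two-session crossing the repeated-measures model
decomposes exactly into between- and within-subject parts:

* interaction: OLS of the difference score (post - pre) on group + sex,
  F on the group term;
* session main effect: F on the intercept of the difference score with
  centred covariates (adjusted grand mean of change = 0);
* group main effect: OLS of the subject mean ((pre + post)/2) on
  group + sex, F on the group term.

The difference-score interaction F equals the mixed two-way interaction F
on balanced data (verified against a subject-dummy OLS oracle in tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortDesign, DTI_METRICS, SESSIONS
from .stats import _f_stats, _orth


class IncompleteDesignError(ValueError):
    """Missing subject/session cells in the DTI table."""


class DegenerateDataError(ValueError):
    """Zero variance makes the requested F statistic undefined."""


def _pivot_metric(table: pd.DataFrame, design: CohortDesign) -> dict:
    """(tract, metric) -> (pre, post) value arrays in design subject order."""
    required = {"subject_id", "session", "tract_label", "metric", "value"}
    if not required.issubset(table.columns):
        raise IncompleteDesignError(f"DTI table needs columns {sorted(required)}")
    wide = table.pivot_table(
        index="subject_id",
        columns=["tract_label", "metric", "session"],
        values="value",
        aggfunc="first",
    )
    subject_ids = design.subject_ids
    missing_subjects = set(subject_ids) - set(wide.index)
    if missing_subjects:
        raise IncompleteDesignError(f"subjects missing from table: {sorted(missing_subjects)}")
    wide = wide.loc[subject_ids]
    cells = {}
    tracts = sorted(table["tract_label"].unique())
    metrics = [m for m in DTI_METRICS if m in set(table["metric"])]
    for tract in tracts:
        for metric in metrics:
            for session in SESSIONS:
                key = (tract, metric, session)
                if key not in wide.columns or wide[key].isna().any():
                    raise IncompleteDesignError(
                        f"incomplete crossing for tract={tract!r}, metric={metric}, "
                        f"session={session}"
                    )
            cells[(tract, metric)] = (
                wide[(tract, metric, "pre")].to_numpy(dtype=float),
                wide[(tract, metric, "post")].to_numpy(dtype=float),
            )
    return cells


def rm_ancova_dti(table: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Repeated-measures ANCOVA per (tract, metric); sex-adjusted F and p.

    Returns one row per tract x metric with columns
    ``F_group, p_group, F_session, p_session, F_interaction, p_interaction``.
    """
    cells = _pivot_metric(table, design)
    keys = list(cells)
    n = design.n_subjects
    diff = np.column_stack([cells[k][1] - cells[k][0] for k in keys])
    avg = np.column_stack([0.5 * (cells[k][1] + cells[k][0]) for k in keys])
    tiny = 1e-12
    for j, key in enumerate(keys):
        scale = max(1.0, np.abs(avg[:, j]).max())
        if diff[:, j].std() <= tiny * scale and avg[:, j].std() <= tiny * scale:
            raise DegenerateDataError(
                f"zero variance for tract={key[0]!r}, metric={key[1]}"
            )

    group = design.group_indicator()
    sex = design.sex_indicator()
    one = np.ones(n)
    q_red = _orth(np.column_stack([one, sex]))
    q_full = _orth(np.column_stack([one, sex, group]))
    df_num = q_full.shape[1] - q_red.shape[1]
    df_den = n - q_full.shape[1]
    if df_den < 1:
        raise IncompleteDesignError("not enough subjects for the model")

    f_inter = _f_stats(diff, q_full, q_red, df_num, df_den)
    # centring is absorbed by the intercept and keeps the group-term sums of
    # squares well conditioned when the metric baseline dwarfs its variance
    f_group = _f_stats(avg - avg.mean(axis=0), q_full, q_red, df_num, df_den)

    # session main effect: intercept of the difference score at centred covariates
    gc = group - group.mean()
    sc = sex - sex.mean()
    q_full_s = _orth(np.column_stack([one, sc, gc]))
    q_red_s = _orth(np.column_stack([sc, gc]))
    df_num_s = q_full_s.shape[1] - q_red_s.shape[1]
    f_sess = _f_stats(diff, q_full_s, q_red_s, df_num_s, df_den)

    rows = []
    for j, (tract, metric) in enumerate(keys):
        rows.append(
            {
                "tract_label": tract,
                "metric": metric,
                "F_group": f_group[j],
                "p_group": float(sps.f.sf(f_group[j], df_num, df_den)),
                "F_session": f_sess[j],
                "p_session": float(sps.f.sf(f_sess[j], df_num_s, df_den)),
                "F_interaction": f_inter[j],
                "p_interaction": float(sps.f.sf(f_inter[j], df_num, df_den)),
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini–Hochberg adjustment of each term's p-values."""
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    for term in ("group", "session", "interaction"):
        col = f"p_{term}"
        out[f"{col}_bh"] = multipletests(out[col].to_numpy(), method="fdr_bh")[1]
    return out
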