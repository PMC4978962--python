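"""Reference cohort summaries for validating the one-sample ratio t-test.

Published group summaries (mean +/- SD of the post/pre FC ratio per
significant link, with the reported two-sided significance bound of the
one-sample t-test against mean 1) from a two-year longitudinal resting-state
study of young binge drinkers: 17 binge drinkers and 22 controls.  The
summaries are consumed as *inputs*: recomputing ``t = (mean-1)/(sd/sqrt(n))``
from the printed numbers and checking it against the printed bound
exercises :func:`plvmotif.stats.one_sample_t_vs1` end to end.

Not every printed row survives recomputation from its own rounded summary
statistics; ``recompute_reference_ttests`` flags each row, and
``CONSISTENT_ROWS`` names the internally consistent ones used as validation
anchors.
"""

from __future__ import annotations

import pandas as pd

from .stats import one_sample_t_vs1

_N = {"bd": 17, "control": 22}

#: (band, link, group, mean, sd, printed two-sided p bound, starred)
_ROWS = [
    ("delta", "FMC-Pc", "bd", 1.07, 0.07, 1e-3, True),
    ("delta", "FMC-Pc", "control", 0.99, 0.05, 2e-1, False),
    ("delta", "FMC-rIPL", "bd", 1.06, 0.08, 9e-3, True),
    ("delta", "FMC-rIPL", "control", 0.97, 0.07, 3e-2, True),
    ("theta", "lIPL-FMC", "bd", 1.08, 0.05, 5e-6, True),
    ("theta", "lIPL-FMC", "control", 0.98, 0.07, 2e-1, False),
    ("theta", "rIPL-FMC", "bd", 1.05, 0.06, 3e-3, True),
    ("theta", "rIPL-FMC", "control", 0.96, 0.04, 2e-3, True),
    ("theta", "rIPL-ACC", "bd", 1.06, 0.05, 9e-4, True),
    ("theta", "rIPL-ACC", "control", 0.97, 0.05, 3e-4, True),
    ("theta", "rIPL-Pc", "bd", 1.07, 0.08, 6e-5, True),
    ("theta", "rIPL-Pc", "control", 0.96, 0.05, 2e-2, True),
    ("beta", "lIPL-rIPL", "bd", 1.08, 0.07, 1e-4, True),
    ("beta", "lIPL-rIPL", "control", 0.96, 0.06, 7e-4, True),
    ("beta", "lIPL-FMC", "bd", 1.12, 0.14, 2e-3, True),
    ("beta", "lIPL-FMC", "control", 0.95, 0.10, 3e-2, True),
    ("beta", "rIPL-FMC", "bd", 1.11, 0.12, 1e-3, True),
    ("beta", "rIPL-FMC", "control", 0.96, 0.09, 6e-2, False),
    ("beta", "rIPL-ACC", "bd", 1.09, 0.07, 3e-4, True),
    ("beta", "rIPL-ACC", "control", 0.96, 0.04, 9e-3, True),
    ("beta", "rIPL-Pc", "bd", 1.11, 0.09, 5e-5, True),
    ("beta", "rIPL-Pc", "control", 0.95, 0.06, 2e-4, True),
]


def reference_ratio_summaries() -> pd.DataFrame:
    """Reference per-link group summaries of the post/pre FC ratio."""
    return pd.DataFrame(
        [
            {
                "band": band,
                "link": link,
                "group": group,
                "mean": mean,
                "sd": sd,
                "n": _N[group],
                "printed_p_bound": bound,
                "starred": starred,
            }
            for band, link, group, mean, sd, bound, starred in _ROWS
        ]
    )


def recompute_reference_ttests() -> pd.DataFrame:
    """Recompute the one-sample t-test against 1 from each summary row.

    Adds ``t``, ``p`` and ``consistent`` (recomputed p below the printed
    bound) columns.  Inconsistent rows reflect the rounding of the printed
    mean/SD, not a defect of the test.
    """
    table = reference_ratio_summaries()
    results = [
        one_sample_t_vs1((row["mean"], row["sd"], row["n"]))
        for _, row in table.iterrows()
    ]
    table["t"] = [r["t"] for r in results]
    table["p"] = [r["p_two_sided"] for r in results]
    table["consistent"] = table["p"] < table["printed_p_bound"]
    return table


#: internally consistent validation rows: short name -> (band, link, group)
CONSISTENT_ROWS = {
    "t_bd_delta_fmc_pc": ("delta", "FMC-Pc", "bd"),
    "t_bd_delta_fmc_ripl": ("delta", "FMC-rIPL", "bd"),
    "t_cn_theta_ripl_fmc": ("theta", "rIPL-FMC", "control"),
    "t_bd_theta_ripl_acc": ("theta", "rIPL-ACC", "bd"),
    "t_cn_theta_ripl_pc": ("theta", "rIPL-Pc", "control"),
    "t_bd_beta_ripl_acc": ("beta", "rIPL-ACC", "bd"),
}


def consistent_reference_tstats() -> dict[str, dict]:
    """t, p and printed bound for the named consistent rows."""
    table = recompute_reference_ttests().set_index(["band", "link", "group"])
    out = {}
    for name, key in CONSISTENT_ROWS.items():
        row = table.loc[key]
        out[name] = {
            "t": float(row["t"]),
            "p": float(row["p"]),
            "printed_p_bound": float(row["printed_p_bound"]),
        }
    return out
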