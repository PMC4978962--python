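"""Calibration and operating-characteristic studies of the pipeline.

These drivers measure, by simulation, the properties the statistical chain
is supposed to have: generator-PLV calibration against the closed form
``I1(kappa)/I0(kappa)``, link-level type-I error of the permutation ANCOVA,
family-wise error of the motif-level correction, recovery of a planted
frontal–parietal hypersynchronisation, and uniformity of the DTI
repeated-measures null.  They are used by the test suite and by
``scripts/acceptance.py``.

Null ratio matrices for the pure error-rate studies are drawn from a
Gaussian exchangeable null rather than the full phase generator: permutation
validity is distribution-free under exchangeability, and this keeps
hundreds of replicates affordable.  The calibration and planted-effect
studies run the phase generator end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import desk_atlas
from .cohort import (
    CohortDesign,
    CouplingPlan,
    expected_plv,
    make_coupling_plan,
    make_design,
    simulate_dti_table,
    simulate_session,
)
from .dti import rm_ancova_dti
from .signal import ConnectivityMatrix, RatioMatrix, TrialSet, plv_matrix, ratio_matrix
from .stats import (
    extract_motifs,
    linkwise_perm_ancova,
    motif_perm_test,
    summarize_motif,
)


def plv_calibration(
    kappas=(0.0, 1.0, 2.0, 5.0),
    n_trials: int = 200,
    fs: float = 1000.0,
    trial_len: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical vs expected PLV of a single coupled pair per concentration.

    One simulated subject, ``n_trials`` trials, no between-subject kappa
    jitter; the empirical PLV is computed through the standard estimator on
    the generated phases.  Runs at the full 1 kHz acquisition rate so the
    finite-sample independence floor (~sqrt(pi/(4T)) per trial) sits well
    below the calibration tolerance at kappa = 0.
    """
    design = make_design(2, 2, {"control": 1, "bd": 1}, seed=0)
    rows = []
    for idx, kappa in enumerate(kappas):
        k = np.zeros((2, 2))
        k[0, 1] = k[1, 0] = kappa
        plan = CouplingPlan(
            n_nodes=2,
            kappa={(g, s): k.copy() for g in ("control", "bd") for s in ("pre", "post")},
            fs=fs,
            trial_len=trial_len,
            n_trials=n_trials,
            subject_kappa_sd=0.0,
        )
        trials = simulate_session(design, plan, "pre", seed=seed + 1000 * idx)
        sid = design.subject_ids[0]
        emp = float(plv_matrix(trials[sid]).plv[0, 1])
        rows.append(
            {
                "kappa": float(kappa),
                "expected": float(expected_plv(kappa)),
                "empirical": emp,
            }
        )
    frame = pd.DataFrame(rows)
    frame["abs_error"] = (frame["empirical"] - frame["expected"]).abs()
    return frame


def _null_ratios(rng, n_subjects: int, n_links: int, sd: float = 0.05) -> np.ndarray:
    return 1.0 + rng.normal(0.0, sd, size=(n_subjects, n_links))


def link_type1_rate(
    n_rep: int = 200,
    n_links: int = 50,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    design: CohortDesign | None = None,
) -> dict:
    """Fraction of null links declared significant by the permutation ANCOVA."""
    if design is None:
        design = make_design(seed=0)
    universe = [(0, i + 1) for i in range(n_links)]
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for rep in range(n_rep):
        y = _null_ratios(rng, design.n_subjects, n_links)
        stats = linkwise_perm_ancova(
            y, design, universe, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31)), keep_perms=False,
        )
        hits += int(stats.significant.sum())
        total += n_links
    rate = hits / total
    se = np.sqrt(alpha * (1 - alpha) / total)
    return {"rate": rate, "alpha": alpha, "se": se, "n_tests": total}


def motif_fwer(
    n_rep: int = 200,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    roi_pair: tuple[str, str] = ("FMC", "rIPL"),
) -> dict:
    """Null family-wise rate of motifs with corrected p < alpha."""
    from .atlas import link_universe

    atlas = desk_atlas()
    design = make_design(seed=0)
    universe = link_universe(atlas, *roi_pair)
    rng = np.random.default_rng(seed)
    families_hit = 0
    for rep in range(n_rep):
        y = _null_ratios(rng, design.n_subjects, len(universe))
        stats = linkwise_perm_ancova(
            y, design, universe, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31)), roi_pair=roi_pair,
        )
        motifs = extract_motifs(stats, atlas)
        motifs = motif_perm_test(motifs, stats, atlas)
        if any(m.corrected_p < alpha for m in motifs):
            families_hit += 1
    rate = families_hit / n_rep
    return {
        "rate": rate,
        "alpha": alpha,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_rep)),
        "n_rep": n_rep,
    }


def _planted_links(atlas) -> list[tuple[int, int]]:
    """Planted connected frontal–parietal tree: 2 FMC + 2 rIPL nodes, 3 links."""
    fmc = atlas.roi_nodes("FMC")
    ripl = atlas.roi_nodes("rIPL")
    return [
        tuple(sorted((fmc[0], ripl[0]))),
        tuple(sorted((fmc[1], ripl[0]))),
        tuple(sorted((fmc[0], ripl[1]))),
    ]


def _subset_plv(trials: TrialSet, nodes: list[int]) -> ConnectivityMatrix:
    """PLV restricted to a node subset (avoids the full-matrix cost)."""
    sub = TrialSet(
        subject_id=trials.subject_id, session=trials.session, band=trials.band,
        fs=trials.fs, data=trials.data[:, nodes, :], kind=trials.kind,
    )
    return plv_matrix(sub)


def planted_recovery_once(
    seed: int,
    n_perm: int = 199,
    alpha: float = 0.05,
    base_kappa: float = 2.0,
    control_post_scale: float = 0.95,
    bd_post_scale: float = 1.15,
    n_trials: int = 20,
) -> dict:
    """Run the full chain once on a planted FMC–rIPL hypersynchronisation.

    Returns whether a corrected-significant motif covering the planted
    nodes was recovered and the motif-degree group summaries.
    """
    atlas = desk_atlas()
    design = make_design(seed=seed)
    planted = _planted_links(atlas)
    plan = make_coupling_plan(
        atlas, planted, base_kappa=base_kappa,
        control_post_scale=control_post_scale, bd_post_scale=bd_post_scale,
        n_trials=n_trials,
    )
    pre = simulate_session(design, plan, "pre", seed=seed)
    post = simulate_session(design, plan, "post", seed=seed)

    roi_pair = ("FMC", "rIPL")
    nodes = sorted(set(atlas.roi_nodes("FMC")) | set(atlas.roi_nodes("rIPL")))
    remap = {n: i for i, n in enumerate(nodes)}
    ratios = {}
    for sid in design.subject_ids:
        r = ratio_matrix(_subset_plv(post[sid], nodes), _subset_plv(pre[sid], nodes))
        full = np.ones((atlas.n_nodes, atlas.n_nodes))
        ix = np.ix_(nodes, nodes)
        full[ix] = r.ratio
        ratios[sid] = RatioMatrix(subject_id=sid, band=plan.band, ratio=full)

    from .atlas import link_universe

    universe = link_universe(atlas, *roi_pair)
    stats = linkwise_perm_ancova(
        ratios, design, universe, n_perm=n_perm, alpha=alpha,
        seed=seed + 7919, roi_pair=roi_pair, band=plan.band,
    )
    motifs = motif_perm_test(extract_motifs(stats, atlas), stats, atlas)
    planted_nodes = {n for link in planted for n in link}
    recovered = None
    for m in motifs:
        if m.corrected_p < alpha and planted_nodes <= set(m.nodes):
            recovered = summarize_motif(m, ratios, design, atlas)
            break
    out = {
        "recovered": recovered is not None,
        "n_motifs": len(motifs),
        "max_mass": max((m.mass for m in motifs), default=0.0),
    }
    if recovered is not None:
        gs = recovered.group_summary
        out.update(
            mass=recovered.mass,
            bd_degree_mean=gs["bd_mean"],
            control_degree_mean=gs["control_mean"],
            cohen_d=recovered.cohen_d,
            accuracy=recovered.accuracy,
            corrected_p=recovered.corrected_p,
            degrees_directional=(gs["bd_mean"] > 1.0 and gs["control_mean"] <= 1.0),
        )
    return out


def planted_recovery(n_seeds: int = 50, seed: int = 0, **kwargs) -> dict:
    """Recovery rate of the planted motif over independent seeded replicates.

    Success requires a corrected-significant motif covering the planted
    node set *and* the qualitative longitudinal pattern: binge-drinking
    degree mean above 1 with the control mean at or below 1.
    """
    records = [
        planted_recovery_once(seed=seed + 1 + k, **kwargs) for k in range(n_seeds)
    ]
    successes = [
        r for r in records if r["recovered"] and r.get("degrees_directional", False)
    ]
    out = {
        "recovery_rate": len(successes) / n_seeds,
        "n_seeds": n_seeds,
        "records": records,
    }
    if successes:
        out["bd_degree_mean"] = float(np.mean([r["bd_degree_mean"] for r in successes]))
        out["control_degree_mean"] = float(
            np.mean([r["control_degree_mean"] for r in successes])
        )
        out["cohen_d"] = float(np.mean([r["cohen_d"] for r in successes]))
        out["accuracy"] = float(np.mean([r["accuracy"] for r in successes]))
    return out


def dti_null_uniformity(
    n_rep: int = 200,
    n_tracts: int = 5,
    seed: int = 0,
) -> dict:
    """KS uniformity check of interaction p-values on null DTI tables."""
    from .cohort import DEFAULT_TRACTS

    design = make_design(seed=0)
    tracts = DEFAULT_TRACTS[:n_tracts]
    pvals = []
    for rep in range(n_rep):
        table = simulate_dti_table(design, tract_labels=tracts, seed=seed + rep)
        res = rm_ancova_dti(table, design)
        pvals.extend(res["p_interaction"].tolist())
    pvals = np.asarray(pvals)
    ks_stat, ks_p = sps.kstest(pvals, "uniform")
    return {
        "ks_stat": float(ks_stat),
        "ks_p": float(ks_p),
        "frac_below_05": float((pvals < 0.05).mean()),
        "n_pvals": len(pvals),
    }


def dti_detection_rate(
    n_rep: int = 50,
    effect_multiple: float = 3.0,
    seed: int = 0,
    n_tracts: int = 1,
) -> float:
    """Power of the interaction test for a planted FA shift (x noise SD)."""
    from .cohort import DEFAULT_TRACTS, DTI_NOISE_SD

    design = make_design(seed=0)
    tracts = DEFAULT_TRACTS[:n_tracts]
    effect = {"FA": effect_multiple * DTI_NOISE_SD["FA"]}
    hits = 0
    for rep in range(n_rep):
        table = simulate_dti_table(
            design, tract_labels=tracts, group_session_effect=effect,
            seed=seed + rep,
        )
        res = rm_ancova_dti(table, design)
        fa = res[res["metric"] == "FA"]
        hits += int((fa["p_interaction"] < 0.05).any())
    return hits / n_rep
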