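"""Synthetic two-group, two-session cohort of phase-coupled narrowband sources.

The generator emulates the data-generating model implicitly assumed by a
longitudinal phase-locking analysis: node-level oscillators whose pairwise
instantaneous phase difference is von Mises distributed.  The concentration
``kappa`` of that distribution maps onto the population phase-locking value
through the mean resultant length ``R(kappa) = I1(kappa)/I0(kappa)``, so the
empirical PLV of a simulated pair is analytically controlled and parameter
recovery becomes a test surface.

Coupling is organised as a forest: the ``kappa > 0`` graph of a plan must be
acyclic.  Phases propagate from a root oscillator down tree edges, each edge
adding a per-trial mean offset plus per-sample von Mises wander, so every
tree edge attains exactly its requested coupling while path-connected pairs
couple at the product of the edge resultant lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .signal import BandSpec, DEFAULT_BANDS, TrialSet

GROUPS = ("control", "bd")
SESSIONS = ("pre", "post")
SEXES = ("F", "M")


class InvalidDesignError(ValueError):
    """Roster parameters violate the cohort contract."""


class InvalidPlanError(ValueError):
    """Coupling plan is not symmetric / non-negative / acyclic."""


@dataclass(frozen=True)
class CohortDesign:
    """Subject roster: the exchangeability unit for every permutation test.

    ``frame`` has one row per subject with columns ``subject_id``, ``group``
    (``control``/``bd``) and ``sex`` (``F``/``M``); both sessions exist for
    every subject by construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "sex"}
        if not required.issubset(self.frame.columns):
            raise InvalidDesignError(f"roster needs columns {sorted(required)}")
        if self.frame["subject_id"].duplicated().any():
            raise InvalidDesignError("subject_ids must be unique")
        counts = self.frame["group"].value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise InvalidDesignError(f"need at least 2 subjects in group {g!r}")
        if not set(self.frame["group"]) <= set(GROUPS):
            raise InvalidDesignError(f"groups must be in {GROUPS}")
        if not set(self.frame["sex"]) <= set(SEXES):
            raise InvalidDesignError(f"sex must be in {SEXES}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def sexes(self) -> np.ndarray:
        return self.frame["sex"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def group_indicator(self) -> np.ndarray:
        """0/1 indicator, 1 for the binge-drinking group."""
        return (self.frame["group"].to_numpy() == "bd").astype(float)

    def sex_indicator(self) -> np.ndarray:
        """0/1 indicator, 1 for male."""
        return (self.frame["sex"].to_numpy() == "M").astype(float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortDesign":
        return cls(pd.read_csv(path))


def make_design(
    n_control: int = 22,
    n_bd: int = 17,
    females_per_group: dict[str, int] | None = None,
    seed: int = 0,
) -> CohortDesign:
    """Build a deterministic roster with the requested group/sex marginals.

    Defaults reproduce a 39-subject cohort of 22 controls (12 female) and
    17 binge drinkers (8 female).  The seed only shuffles which subjects
    within a group are female; marginals are exact.
    """
    if females_per_group is None:
        females_per_group = {"control": 12, "bd": 8}
    if n_control < 2 or n_bd < 2:
        raise InvalidDesignError("each group needs at least 2 subjects")
    sizes = {"control": n_control, "bd": n_bd}
    prefixes = {"control": "C", "bd": "B"}
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        n = sizes[group]
        n_f = int(females_per_group.get(group, 0))
        if n_f < 0 or n_f > n:
            raise InvalidDesignError(
                f"females_per_group[{group!r}]={n_f} exceeds group size {n}"
            )
        sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(sex)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefixes[group]}{i + 1:02d}",
                    "group": group,
                    "sex": sex[i],
                }
            )
    return CohortDesign(pd.DataFrame(rows))


def expected_plv(kappa) -> np.ndarray | float:
    """Population PLV of a von Mises phase offset: I1(kappa)/I0(kappa).

    Monotone increasing, 0 at kappa=0, -> 1 as kappa -> inf.  Uses
    exponentially scaled Bessel functions so large concentrations do not
    overflow.
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(~np.isfinite(k)) or np.any(k < 0):
        raise ValueError("kappa must be finite and >= 0")
    out = special.ive(1, k) / special.ive(0, k)
    return float(out) if np.isscalar(kappa) else out


@dataclass
class CouplingPlan:
    """Per (group, session) symmetric node-by-node von Mises concentrations.

    ``kappa[(group, session)]`` is an ``n_nodes x n_nodes`` symmetric array;
    zero means uncoupled.  The positive-kappa graph must be a forest (see
    module docstring).  ``subject_kappa_sd`` is the standard deviation of a
    per-subject, per-session, per-edge lognormal multiplier emulating
    between-subject coupling variability.  ``phase_diffusion`` (rad^2 per
    sample) sets the root oscillators' phase-diffusion rate; the default is
    large so that uncoupled pairs sit at the finite-sample independence
    floor of the PLV estimator.
    """

    n_nodes: int
    kappa: dict[tuple[str, str], np.ndarray]
    band: BandSpec = DEFAULT_BANDS["theta"]
    fs: float = 250.0
    trial_len: float = 4.0
    n_trials: int = 20
    subject_kappa_sd: float = 0.06
    phase_diffusion: float = 2.0
    noise_sd: float = 0.3
    mode: str = "phases"  # "phases" or "signal"

    def __post_init__(self) -> None:
        if self.mode not in ("phases", "signal"):
            raise InvalidPlanError("mode must be 'phases' or 'signal'")
        n_samp = self.fs * self.trial_len
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise InvalidPlanError("fs * trial_len must be an integer sample count")
        for key, k in self.kappa.items():
            k = np.asarray(k, dtype=float)
            if k.shape != (self.n_nodes, self.n_nodes):
                raise InvalidPlanError(f"kappa[{key}] has shape {k.shape}")
            if not np.all(np.isfinite(k)) or np.any(k < 0):
                raise InvalidPlanError(f"kappa[{key}] must be finite and >= 0")
            if not np.allclose(k, k.T):
                raise InvalidPlanError(f"kappa[{key}] must be symmetric")
            self.kappa[key] = k
            _coupling_forest(k, self.n_nodes)  # raises on cycles

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_len))


def _coupling_forest(kappa: np.ndarray, n_nodes: int) -> list[tuple[int, int]]:
    """Order coupled edges parent->child by BFS; raise if the graph has a cycle."""
    iu = np.triu_indices(n_nodes, 1)
    edges = [
        (int(i), int(j)) for i, j in zip(*iu) if kappa[i, j] > 0
    ]
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    seen: set[int] = set()
    order: list[tuple[int, int]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        seen.add(start)
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in sorted(adj[u]):
                if v in seen:
                    continue
                seen.add(v)
                order.append((u, v))
                queue.append(v)
    if len(order) != len(edges):
        raise InvalidPlanError("coupled (kappa > 0) graph must be acyclic")
    return order


def simulate_session(
    design: CohortDesign,
    plan: CouplingPlan,
    session: str,
    seed: int = 0,
) -> dict[str, TrialSet]:
    """Simulate one session's trials for every subject.

    Per subject: root-node phases follow ``2*pi*f0*t`` plus a Brownian phase
    walk; each coupled child node's phase is its parent's plus a per-trial
    uniform mean offset plus i.i.d. per-sample von Mises wander with the
    subject's edge concentration.  In ``signal`` mode the returned data are
    ``cos(phase)`` plus white noise; in ``phases`` mode the phases themselves.
    """
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    n = plan.n_nodes
    n_samp = plan.n_samples
    f0 = 0.5 * (plan.band.f_lo + plan.band.f_hi)
    base = 2.0 * np.pi * f0 * np.arange(n_samp) / plan.fs
    session_code = SESSIONS.index(session)
    root_ss = np.random.SeedSequence([int(seed), session_code])
    children = root_ss.spawn(design.n_subjects)
    out: dict[str, TrialSet] = {}
    for subj_idx, (sid, group) in enumerate(zip(design.subject_ids, design.groups)):
        rng = np.random.default_rng(children[subj_idx])
        kappa = plan.kappa[(group, session)]
        edges = _coupling_forest(kappa, n)
        kappa_subj = {
            e: kappa[e] * np.exp(rng.normal(0.0, plan.subject_kappa_sd))
            for e in edges
        }
        child_nodes = {j for _, j in edges}
        roots = [i for i in range(n) if i not in child_nodes]
        phases = np.empty((plan.n_trials, n, n_samp))
        theta0 = rng.uniform(0.0, 2.0 * np.pi, size=(plan.n_trials, len(roots), 1))
        walk = np.cumsum(
            rng.normal(
                0.0,
                np.sqrt(plan.phase_diffusion),
                size=(plan.n_trials, len(roots), n_samp),
            ),
            axis=-1,
        )
        phases[:, roots, :] = base + theta0 + walk
        for (parent, child) in edges:
            mu = rng.uniform(-np.pi, np.pi, size=(plan.n_trials, 1))
            delta = rng.vonmises(0.0, kappa_subj[(parent, child)],
                                 size=(plan.n_trials, n_samp))
            phases[:, child, :] = phases[:, parent, :] + mu + delta
        if plan.mode == "signal":
            data = np.cos(phases)
            data += rng.normal(0.0, plan.noise_sd, size=data.shape)
            kind = "signal"
        else:
            data = phases
            kind = "phase"
        out[sid] = TrialSet(
            subject_id=sid, session=session, band=plan.band, fs=plan.fs,
            data=data, kind=kind,
        )
    return out


def simulate_cohort(
    design: CohortDesign, plan: CouplingPlan, seed: int = 0
) -> dict[tuple[str, str], TrialSet]:
    """Both sessions for every subject, keyed by (subject_id, session)."""
    out: dict[tuple[str, str], TrialSet] = {}
    for session in SESSIONS:
        for sid, ts in simulate_session(design, plan, session, seed).items():
            out[(sid, session)] = ts
    return out


def make_coupling_plan(
    atlas,
    planted_links: list[tuple[int, int]],
    base_kappa: float = 2.0,
    control_post_scale: float = 0.95,
    bd_post_scale: float = 1.15,
    **plan_kwargs,
) -> CouplingPlan:
    """Plan with a planted longitudinal group difference on a set of links.

    Both groups share ``base_kappa`` on the planted links at the pre session;
    at post the control group's concentration shrinks slightly (maturation,
    FC ratio <= 1) while the binge-drinking group's grows (hypersynchrony,
    FC ratio > 1).  All other pairs stay uncoupled.
    """
    n = atlas.n_nodes
    k_pre = np.zeros((n, n))
    for i, j in planted_links:
        k_pre[i, j] = k_pre[j, i] = base_kappa
    kappa = {
        ("control", "pre"): k_pre,
        ("bd", "pre"): k_pre.copy(),
        ("control", "post"): k_pre * control_post_scale,
        ("bd", "post"): k_pre * bd_post_scale,
    }
    return CouplingPlan(n_nodes=n, kappa=kappa, **plan_kwargs)


def null_coupling_plan(atlas, **plan_kwargs) -> CouplingPlan:
    """Plan with no coupling anywhere (all pairs independent)."""
    n = atlas.n_nodes
    zero = np.zeros((n, n))
    kappa = {(g, s): zero.copy() for g in GROUPS for s in SESSIONS}
    return CouplingPlan(n_nodes=n, kappa=kappa, **plan_kwargs)


# ---------------------------------------------------------------------------
# DTI metric tables

DTI_METRICS = ("FA", "MD", "RD", "AD")

#: typical young-adult white-matter baselines; FA dimensionless, rest mm^2/s
DTI_BASELINES = {"FA": 0.45, "MD": 7.5e-4, "RD": 6.0e-4, "AD": 1.1e-3}

#: default per-metric noise SDs (between-subject + measurement)
DTI_NOISE_SD = {"FA": 0.02, "MD": 3.0e-5, "RD": 3.0e-5, "AD": 4.0e-5}

#: 20 major white-matter tracts following the JHU tractography naming style
DEFAULT_TRACTS = tuple(
    f"{name} {side}"
    for name in (
        "Anterior thalamic radiation",
        "Corticospinal tract",
        "Cingulum (cingulate gyrus)",
        "Cingulum (hippocampus)",
        "Inferior fronto-occipital fasciculus",
        "Inferior longitudinal fasciculus",
        "Superior longitudinal fasciculus",
        "Uncinate fasciculus",
        "Superior longitudinal fasciculus (temporal part)",
    )
    for side in ("L", "R")
) + ("Forceps major", "Forceps minor")


def simulate_dti_table(
    design: CohortDesign,
    tract_labels: tuple[str, ...] = DEFAULT_TRACTS,
    group_session_effect: dict[str, float] | None = None,
    noise_sd: dict[str, float] | None = None,
    baselines: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete subjects x sessions x tracts x metrics table of DTI scalars.

    ``group_session_effect[metric]`` is added to the binge-drinking group's
    post-session values (a planted group-by-session interaction); the default
    is no effect, matching a null structural arm.
    """
    effects = dict.fromkeys(DTI_METRICS, 0.0)
    if group_session_effect:
        effects.update(group_session_effect)
    sds = dict(DTI_NOISE_SD)
    if noise_sd:
        sds.update(noise_sd)
    bases = dict(DTI_BASELINES)
    if baselines:
        bases.update(baselines)
    if not 0.0 <= bases["FA"] <= 1.0:
        raise ValueError("FA baseline must lie in [0, 1]")
    if any(sds[m] < 0 for m in DTI_METRICS):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, group in zip(design.subject_ids, design.groups):
        for session in SESSIONS:
            for tract in tract_labels:
                for metric in DTI_METRICS:
                    value = bases[metric] + rng.normal(0.0, sds[metric])
                    if group == "bd" and session == "post":
                        value += effects[metric]
                    if metric == "FA":
                        value = float(np.clip(value, 0.0, 1.0))
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": session,
                            "tract_label": tract,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
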