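"""Link-wise permutation ANCOVA, motif extraction and motif-level inference.

The inferential chain for one frequency band and one ROI pair:

1. Per link (node pair in the ROI-pair universe), an ANCOVA of the
   post/pre FC ratio on group with sex as covariate; significance from a
   Freedman–Lane permutation null (residuals of the sex-only model are
   permuted across subjects, 5000 permutations by default, add-one
   p-value convention).
2. Links with p < alpha form a graph whose connected components are
   candidate *motifs*; a component survives iff it covers at least 25% of
   the nodes of each ROI of the pair and its significant links number at
   least 10% of the link universe.
3. Family-wise error across motifs is controlled by a max-statistic
   permutation test: the same permutations re-enter the link test +
   extraction procedure and the maximum motif mass (sum of member-link F
   statistics) per permutation forms the corrected null.
4. Each surviving motif is summarised per subject by its *degree* — the
   mean PLV ratio over the motif's links — followed by a group ANCOVA
   (Bonferroni-corrected over the five frequency bands), Cohen's d,
   one-sample t-tests of each group's degree against 1, and a
   leave-one-out logistic-regression classification accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .atlas import AtlasLayout, motif_centroid
from .cohort import CohortDesign
from .signal import BandSpec, RatioMatrix


class DesignError(ValueError):
    """Group structure unusable for the requested test."""


class UndefinedEffectError(ValueError):
    """Effect size undefined (zero pooled variance)."""


# ---------------------------------------------------------------------------
# link-wise permutation ANCOVA


@dataclass
class LinkStatMap:
    """Per-link group-effect F and permutation p over one link universe."""

    universe: list[tuple[int, int]]
    f_obs: np.ndarray
    p: np.ndarray
    alpha: float
    n_perm: int
    roi_pair: tuple[str, str] = ("", "")
    band: BandSpec | None = None
    perm_f: np.ndarray | None = None  # (n_perm, n_links), kept for motif test

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha

    def to_frame(self, atlas: AtlasLayout | None = None) -> pd.DataFrame:
        rows = []
        for idx, (i, j) in enumerate(self.universe):
            row = {"node_i": i, "node_j": j,
                   "f": self.f_obs[idx], "p": self.p[idx],
                   "significant": bool(self.significant[idx])}
            if atlas is not None:
                row["node_i_id"] = atlas.node_ids[i]
                row["node_j_id"] = atlas.node_ids[j]
            rows.append(row)
        return pd.DataFrame(rows)


def stack_ratios(
    ratios: dict[str, RatioMatrix],
    subject_ids: list[str],
    universe: list[tuple[int, int]],
) -> np.ndarray:
    """Subjects x links matrix of ratio values in design order."""
    out = np.empty((len(subject_ids), len(universe)))
    for s, sid in enumerate(subject_ids):
        try:
            mat = ratios[sid]
        except KeyError:
            raise DesignError(f"no ratio matrix for subject {sid!r}") from None
        arr = mat.ratio if isinstance(mat, RatioMatrix) else np.asarray(mat)
        for l, (i, j) in enumerate(universe):
            out[s, l] = arr[i, j]
    return out


def _orth(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _f_stats(
    y: np.ndarray,
    q_full: np.ndarray,
    q_red: np.ndarray,
    df_num: int,
    df_den: int,
) -> np.ndarray:
    """Vectorised extra-sum-of-squares F for many responses sharing a design."""
    tot = np.einsum("nl,nl->l", y, y)
    rss_full = tot - np.einsum("kl,kl->l", q_full.T @ y, q_full.T @ y)
    rss_red = tot - np.einsum("kl,kl->l", q_red.T @ y, q_red.T @ y)
    num = (rss_red - rss_full) / df_num
    den = rss_full / df_den
    scale = np.maximum(tot / max(df_den, 1), 1e-300)
    f = np.zeros_like(num)
    ok = den > 1e-12 * scale
    f[ok] = num[ok] / den[ok]
    f[~ok & (num > 1e-12 * scale)] = np.inf
    return np.maximum(f, 0.0)


def linkwise_perm_ancova(
    ratios,
    design: CohortDesign,
    universe: list[tuple[int, int]],
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    keep_perms: bool = True,
    roi_pair: tuple[str, str] = ("", ""),
    band: BandSpec | None = None,
) -> LinkStatMap:
    """Group-effect permutation ANCOVA on FC ratios, one test per link.

    ``ratios`` is either a mapping subject_id -> RatioMatrix (or full
    node x node array) or a pre-stacked subjects x links array in design
    order.  The observed statistic is the OLS F for the group term in
    ``ratio ~ group + sex``; the null is built by Freedman–Lane residual
    permutation (permute residuals of the sex-only fit, whole subjects
    exchanged).  p-values use the add-one convention, so their support is
    ``{1/(B+1), ..., 1}``.
    """
    if not universe:
        raise ValueError("link universe is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subject_ids = design.subject_ids
    if isinstance(ratios, np.ndarray):
        y = np.asarray(ratios, dtype=float)
        if y.shape != (len(subject_ids), len(universe)):
            raise DesignError(
                f"stacked ratios must be {len(subject_ids)} x {len(universe)}"
            )
    else:
        y = stack_ratios(ratios, subject_ids, universe)
    n = len(subject_ids)
    counts = pd.Series(design.groups).value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise DesignError("need at least 2 subjects in each of the two groups")

    group = design.group_indicator()
    sex = design.sex_indicator()
    intercept = np.ones(n)
    x_red = _orth(np.column_stack([intercept, sex]))
    x_full = _orth(np.column_stack([intercept, sex, group]))
    df_num = x_full.shape[1] - x_red.shape[1]
    df_den = n - x_full.shape[1]
    if df_num < 1 or df_den < 1:
        raise DesignError("design matrix leaves no degrees of freedom")

    # degenerate links: no variation at all -> test undefined, never significant
    const = y.std(axis=0) <= 1e-12 * np.maximum(1.0, np.abs(y).max())
    if const.any():
        warnings.warn(
            f"{int(const.sum())} links have constant ratios across subjects; "
            "flagged not-significant",
            RuntimeWarning,
            stacklevel=2,
        )

    f_obs = _f_stats(y, x_full, x_red, df_num, df_den)
    fitted_red = x_red @ (x_red.T @ y)
    resid_red = y - fitted_red
    rng = np.random.default_rng(seed)
    perm_f = np.empty((n_perm, len(universe)))
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted_red + resid_red[perm]
        perm_f[b] = _f_stats(y_star, x_full, x_red, df_num, df_den)
    exceed = (perm_f >= f_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[const] = 1.0
    f_obs = np.where(const, 0.0, f_obs)
    return LinkStatMap(
        universe=list(universe), f_obs=f_obs, p=p, alpha=alpha, n_perm=n_perm,
        roi_pair=roi_pair, band=band, perm_f=perm_f if keep_perms else None,
    )


# ---------------------------------------------------------------------------
# motif extraction


@dataclass
class Motif:
    """Connected sub-network of significant links within one ROI pair."""

    roi_pair: tuple[str, str]
    nodes: tuple[int, ...]
    links: tuple[tuple[int, int], ...]
    mass: float
    band: BandSpec | None = None
    corrected_p: float | None = None
    degrees: pd.Series | None = None
    group_summary: dict | None = None
    cohen_d: float | None = None
    accuracy: float | None = None
    centroids: dict | None = None


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _components(links: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Connected components of the link graph, as lists of links."""
    nodes = {n for link in links for n in link}
    uf = _UnionFind(nodes)
    for i, j in links:
        uf.union(i, j)
    comps: dict[int, list[tuple[int, int]]] = {}
    for link in links:
        comps.setdefault(uf.find(link[0]), []).append(link)
    return [comps[root] for root in sorted(comps)]


def _passes_criteria(
    comp_links: list[tuple[int, int]],
    roi_nodes: tuple[set[int], set[int]],
    universe_size: int,
    node_frac: float,
    link_frac: float,
    intra: bool,
    denominator: str,
) -> bool:
    comp_nodes = {n for link in comp_links for n in link}
    nodes_a = comp_nodes & roi_nodes[0]
    if len(nodes_a) < node_frac * len(roi_nodes[0]):
        return False
    if not intra:
        nodes_b = comp_nodes & roi_nodes[1]
        if len(nodes_b) < node_frac * len(roi_nodes[1]):
            return False
    if denominator == "universe":
        denom = universe_size
    elif intra:
        denom = len(nodes_a) * (len(nodes_a) - 1) // 2
    else:
        denom = len(nodes_a) * len(comp_nodes & roi_nodes[1])
    return denom > 0 and len(comp_links) >= link_frac * denom


def extract_motifs(
    stats: LinkStatMap,
    atlas: AtlasLayout,
    node_frac: float = 0.25,
    link_frac: float = 0.10,
    denominator: str = "universe",
) -> list[Motif]:
    """Connected significant components passing the size criteria.

    A component is a motif iff (a) for each ROI of the pair it contains at
    least ``node_frac`` of that ROI's nodes, (b) its significant links
    number at least ``link_frac`` of the link universe (or of the
    component-internal pair count with ``denominator='component'``), and
    (c) it is connected, which holds by construction.  Mass is the sum of
    member-link F statistics.  An empty result is a valid outcome.
    """
    roi_a, roi_b = stats.roi_pair
    if not roi_a:
        raise ValueError("LinkStatMap must carry its roi_pair for extraction")
    roi_nodes = (set(atlas.roi_nodes(roi_a)), set(atlas.roi_nodes(roi_b)))
    intra = roi_a == roi_b
    f_by_link = dict(zip(stats.universe, stats.f_obs))
    sig_links = [link for link, s in zip(stats.universe, stats.significant) if s]
    motifs = []
    for comp in _components(sig_links):
        if _passes_criteria(comp, roi_nodes, len(stats.universe),
                            node_frac, link_frac, intra, denominator):
            nodes = tuple(sorted({n for link in comp for n in link}))
            links = tuple(sorted(comp))
            mass = float(sum(f_by_link[l] for l in links))
            motifs.append(Motif(roi_pair=stats.roi_pair, nodes=nodes,
                                links=links, mass=mass, band=stats.band))
    motifs.sort(key=lambda m: -m.mass)
    return motifs


# ---------------------------------------------------------------------------
# motif-level permutation correction


def _perm_significance_cutoffs(perm_f: np.ndarray, alpha: float) -> np.ndarray:
    """Per-link F cutoff equivalent to add-one permutation p < alpha.

    A statistic F is significant against a link's permutation distribution
    iff the number of permuted values >= F is at most ``cmax``, i.e. iff
    F strictly exceeds the (cmax+1)-th largest permuted value.
    """
    n_perm = perm_f.shape[0]
    cmax = int(np.floor(alpha * (n_perm + 1) - 1.0 - 1e-9))
    if cmax < 0:
        return np.full(perm_f.shape[1], np.inf)
    if cmax >= n_perm:
        return np.full(perm_f.shape[1], -np.inf)
    sorted_desc = -np.sort(-perm_f, axis=0)
    return sorted_desc[cmax]


def motif_perm_test(
    motifs: list[Motif],
    stats: LinkStatMap,
    atlas: AtlasLayout,
    node_frac: float = 0.25,
    link_frac: float = 0.10,
    denominator: str = "universe",
) -> list[Motif]:
    """Max-mass permutation correction of motif significance.

    For every stored permutation the link test + motif extraction is
    replayed: a link counts as significant under permutation ``b`` iff its
    permuted F would itself reach p < alpha against the same permutation
    distribution, and the maximum surviving motif mass (0 if none) forms
    the family-wise null.  Corrected p of an observed motif is
    ``(1 + #{max mass >= observed mass}) / (n_perm + 1)``.
    """
    if not motifs:
        return []
    if stats.perm_f is None:
        raise ValueError("run linkwise_perm_ancova with keep_perms=True first")
    if stats.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    roi_a, roi_b = stats.roi_pair
    roi_nodes = (set(atlas.roi_nodes(roi_a)), set(atlas.roi_nodes(roi_b)))
    intra = roi_a == roi_b
    cutoffs = _perm_significance_cutoffs(stats.perm_f, stats.alpha)
    universe = stats.universe
    max_mass = np.zeros(stats.n_perm)
    for b in range(stats.n_perm):
        fb = stats.perm_f[b]
        sig_idx = np.flatnonzero(fb > cutoffs)
        if sig_idx.size == 0:
            continue
        sig_links = [universe[i] for i in sig_idx]
        f_by_link = {universe[i]: fb[i] for i in sig_idx}
        best = 0.0
        for comp in _components(sig_links):
            if _passes_criteria(comp, roi_nodes, len(universe),
                                node_frac, link_frac, intra, denominator):
                best = max(best, sum(f_by_link[l] for l in comp))
        max_mass[b] = best
    out = []
    for motif in motifs:
        exceed = int((max_mass >= motif.mass).sum())
        out.append(replace(motif, corrected_p=(1.0 + exceed) / (stats.n_perm + 1.0)))
    return out


# ---------------------------------------------------------------------------
# motif summaries


def motif_degree(motif: Motif, ratios: dict[str, RatioMatrix]) -> pd.Series:
    """Per-subject degree: mean PLV ratio across the motif's links."""
    values = {}
    for sid, mat in ratios.items():
        arr = mat.ratio if isinstance(mat, RatioMatrix) else np.asarray(mat)
        values[sid] = float(np.mean([arr[i, j] for i, j in motif.links]))
    return pd.Series(values, name="degree")


def cohens_d(x_bd: np.ndarray, x_control: np.ndarray) -> float:
    """Standardised mean difference (BD minus control) with pooled SD."""
    x_bd = np.asarray(x_bd, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    n1, n2 = len(x_bd), len(x_control)
    if n1 < 2 or n2 < 2:
        raise DesignError("need at least 2 subjects per group for Cohen's d")
    pooled = np.sqrt(
        ((n1 - 1) * x_bd.var(ddof=1) + (n2 - 1) * x_control.var(ddof=1))
        / (n1 + n2 - 2)
    )
    if pooled <= 0.0:
        raise UndefinedEffectError("pooled SD is zero; effect size undefined")
    return float((x_bd.mean() - x_control.mean()) / pooled)


def degree_group_test(
    degrees: pd.Series,
    design: CohortDesign,
    n_bands: int = 5,
) -> dict:
    """Group ANCOVA on motif degree with sex covariate, Bonferroni over bands.

    Returns the F and raw p for the group term of ``degree ~ group + sex``,
    the Bonferroni-corrected p (``min(1, n_bands * p)``) accounting for the
    five frequency bands analysed, Cohen's d, and the per-group summaries.
    """
    import statsmodels.api as sm

    y = degrees.loc[design.subject_ids].to_numpy(dtype=float)
    group = design.group_indicator()
    sex = design.sex_indicator()
    if len(np.unique(group)) < 2:
        raise DesignError("both groups must be represented")
    x = sm.add_constant(np.column_stack([sex, group]))
    fit = sm.OLS(y, x).fit()
    f_res = fit.f_test(np.array([[0.0, 0.0, 1.0]]))
    f_stat = float(np.squeeze(f_res.fvalue))
    p_raw = float(np.squeeze(f_res.pvalue))
    bd = y[group == 1.0]
    cn = y[group == 0.0]
    return {
        "F": f_stat,
        "p_raw": p_raw,
        "p_corrected": min(1.0, n_bands * p_raw),
        "cohen_d": cohens_d(bd, cn),
        "bd_mean": float(bd.mean()),
        "bd_sd": float(bd.std(ddof=1)),
        "bd_n": int(len(bd)),
        "control_mean": float(cn.mean()),
        "control_sd": float(cn.std(ddof=1)),
        "control_n": int(len(cn)),
    }


def one_sample_t_vs1(values) -> dict:
    """Two-sided one-sample t-test of a set of ratios against mean 1.

    ``values`` is either per-subject values or a ``(mean, sd, n)`` summary
    triple, so the test can be recomputed from published group summaries.
    """
    if isinstance(values, tuple) and len(values) == 3:
        mean, sd, n = float(values[0]), float(values[1]), int(values[2])
    else:
        arr = np.asarray(values, dtype=float)
        mean, sd, n = float(arr.mean()), float(arr.std(ddof=1)), len(arr)
    if n < 2:
        raise DesignError("need n >= 2 for a one-sample t-test")
    if sd <= 0.0:
        raise UndefinedEffectError("zero SD; t-test degenerate")
    t = (mean - 1.0) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p_two_sided": float(p), "df": n - 1}


def loo_logreg_accuracy(degrees, groups, seed: int = 0) -> float:
    """Leave-one-out logistic-regression classification accuracy.

    For each subject an unpenalised logistic regression of group on degree
    is fit on the remaining subjects and the held-out label predicted at
    probability threshold 0.5 (ties classify as control).  With a constant
    predictor the fit reduces to the intercept and predicts the fold's
    majority class.
    """
    x = np.asarray(degrees, dtype=float).reshape(-1, 1)
    y = np.asarray([1 if g in ("bd", 1, True) else 0 for g in groups])
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise DesignError("need at least 2 subjects in each group")
    n = len(y)
    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for held in range(n):
            mask = np.ones(n, dtype=bool)
            mask[held] = False
            # effectively unpenalised (C -> inf) so a clear margin classifies
            # perfectly and a constant predictor falls back to the intercept
            clf = LogisticRegression(C=1e12, solver="lbfgs", max_iter=1000)
            clf.fit(x[mask], y[mask])
            p_bd = clf.predict_proba(x[held : held + 1])[0][list(clf.classes_).index(1)]
            pred = 1 if p_bd > 0.5 else 0
            correct += int(pred == y[held])
    return correct / n


def summarize_motif(
    motif: Motif,
    ratios: dict[str, RatioMatrix],
    design: CohortDesign,
    atlas: AtlasLayout,
    n_bands: int = 5,
) -> Motif:
    """Attach degree, group statistics, classification and centroids."""
    degrees = motif_degree(motif, ratios)
    group_test = degree_group_test(degrees, design, n_bands=n_bands)
    bd_ids = [s for s, g in zip(design.subject_ids, design.groups) if g == "bd"]
    cn_ids = [s for s, g in zip(design.subject_ids, design.groups) if g == "control"]
    group_test["bd_t_vs1"] = one_sample_t_vs1(degrees.loc[bd_ids].to_numpy())
    group_test["control_t_vs1"] = one_sample_t_vs1(degrees.loc[cn_ids].to_numpy())
    accuracy = loo_logreg_accuracy(
        degrees.loc[design.subject_ids].to_numpy(), design.groups
    )
    centroids = motif_centroid(motif.nodes, atlas)
    return replace(
        motif,
        degrees=degrees,
        group_summary=group_test,
        cohen_d=group_test["cohen_d"],
        accuracy=accuracy,
        centroids=centroids,
    )
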