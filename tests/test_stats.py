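"""Link-wise permutation ANCOVA, motif machinery, and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from plvmotif.atlas import default_atlas, link_universe
from plvmotif.cohort import make_design
from plvmotif.stats import (
    DesignError,
    LinkStatMap,
    Motif,
    UndefinedEffectError,
    cohens_d,
    degree_group_test,
    extract_motifs,
    linkwise_perm_ancova,
    loo_logreg_accuracy,
    motif_degree,
    motif_perm_test,
    one_sample_t_vs1,
)


def standardized(rng, n):
    z = rng.normal(size=n)
    return (z - z.mean()) / z.std(ddof=1)


def with_moments(rng, mean, sd, n):
    return mean + sd * standardized(rng, n)


class TestLinkwisePermAncova:
    def test_observed_f_matches_statsmodels(self, design39, rng):
        import statsmodels.api as sm

        y = 1 + 0.1 * rng.normal(size=(39, 5))
        universe = [(0, i + 1) for i in range(5)]
        stats = linkwise_perm_ancova(y, design39, universe, n_perm=5, seed=0)
        group = design39.group_indicator()
        sex = design39.sex_indicator()
        x = sm.add_constant(np.column_stack([sex, group]))
        for l in range(5):
            fit = sm.OLS(y[:, l], x).fit()
            f_sm = float(np.squeeze(fit.f_test([[0, 0, 1]]).fvalue))
            assert stats.f_obs[l] == pytest.approx(f_sm, rel=1e-8)

    def test_planted_separation_reaches_minimum_p(self, design39, rng):
        n_perm = 199
        y = 1 + 0.01 * rng.normal(size=(39, 3))
        bd = design39.group_indicator().astype(bool)
        y[bd, 1] += 1.0  # ~100 pooled SDs on link 1
        stats = linkwise_perm_ancova(
            y, design39, [(0, 1), (0, 2), (0, 3)], n_perm=n_perm, seed=0
        )
        assert stats.p[1] == pytest.approx(1.0 / (n_perm + 1))
        assert stats.significant[1]

    def test_p_support_with_19_permutations(self, design39, rng):
        y = 1 + 0.05 * rng.normal(size=(39, 10))
        universe = [(0, i + 1) for i in range(10)]
        stats = linkwise_perm_ancova(y, design39, universe, n_perm=19, seed=1)
        support = np.arange(1, 21) / 20.0
        assert np.all(np.isin(np.round(stats.p, 10), np.round(support, 10)))

    def test_constant_link_flagged_not_significant(self, design39, rng):
        y = 1 + 0.05 * rng.normal(size=(39, 2))
        y[:, 0] = 1.0
        with pytest.warns(RuntimeWarning, match="constant"):
            stats = linkwise_perm_ancova(y, design39, [(0, 1), (0, 2)], n_perm=19)
        assert not stats.significant[0]
        assert stats.p[0] == 1.0

    def test_empty_universe_rejected(self, design39):
        with pytest.raises(ValueError):
            linkwise_perm_ancova(np.ones((39, 0)), design39, [], n_perm=5)


def two_roi_atlas(n_a=8, n_b=8):
    return default_atlas(
        {"Pc": 1, "PCC": 1, "ACC": 1, "FMC": n_a, "lIPL": 1, "rIPL": n_b}
    )


def stat_map(atlas, sig_links, f_sig=10.0):
    universe = link_universe(atlas, "FMC", "rIPL")
    sig = set(sig_links)
    f_obs = np.array([f_sig if l in sig else 0.5 for l in universe])
    p = np.array([0.01 if l in sig else 0.5 for l in universe])
    return LinkStatMap(
        universe=universe, f_obs=f_obs, p=p, alpha=0.05, n_perm=199,
        roi_pair=("FMC", "rIPL"),
    )


class TestExtractMotifs:
    def test_density_boundary_rejects_three_links(self):
        atlas = two_roi_atlas()
        fmc = atlas.roi_nodes("FMC")
        ripl = atlas.roi_nodes("rIPL")
        # 2+2 nodes, 3 links: node coverage exactly 25% but 3/64 < 10%
        links = [
            tuple(sorted((fmc[0], ripl[0]))),
            tuple(sorted((fmc[0], ripl[1]))),
            tuple(sorted((fmc[1], ripl[0]))),
        ]
        assert extract_motifs(stat_map(atlas, links), atlas) == []

    def test_density_boundary_accepts_seven_links(self):
        atlas = two_roi_atlas()
        fmc = atlas.roi_nodes("FMC")
        ripl = atlas.roi_nodes("rIPL")
        links = [
            tuple(sorted((fmc[a], ripl[b])))
            for a, b in [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (2, 0), (2, 1)]
        ]
        motifs = extract_motifs(stat_map(atlas, links), atlas)
        assert len(motifs) == 1
        assert set(motifs[0].links) == set(links)
        assert motifs[0].mass == pytest.approx(7 * 10.0)

    def test_components_evaluated_separately(self):
        atlas = two_roi_atlas()
        fmc = atlas.roi_nodes("FMC")
        ripl = atlas.roi_nodes("rIPL")
        comp4 = [
            tuple(sorted((fmc[a], ripl[b])))
            for a, b in [(0, 0), (0, 1), (1, 0), (1, 1)]
        ]
        comp3 = [
            tuple(sorted((fmc[a], ripl[b])))
            for a, b in [(4, 4), (4, 5), (5, 4)]
        ]
        motifs = extract_motifs(stat_map(atlas, comp4 + comp3), atlas)
        # the 3-link component always fails the 10% density rule
        assert all(set(m.links) != set(comp3) for m in motifs)
        assert len(motifs) <= 1

    def test_agrees_with_networkx_enumeration_oracle(self, rng):
        import networkx as nx

        atlas = two_roi_atlas(5, 5)
        universe = link_universe(atlas, "FMC", "rIPL")
        roi_a = set(atlas.roi_nodes("FMC"))
        roi_b = set(atlas.roi_nodes("rIPL"))
        for _ in range(60):
            sig = rng.random(len(universe)) < 0.3
            f_obs = rng.uniform(1, 10, size=len(universe))
            stats = LinkStatMap(
                universe=universe, f_obs=f_obs,
                p=np.where(sig, 0.01, 0.5), alpha=0.05, n_perm=199,
                roi_pair=("FMC", "rIPL"),
            )
            got = {
                (frozenset(m.nodes), round(m.mass, 9))
                for m in extract_motifs(stats, atlas)
            }
            graph = nx.Graph()
            for link, s in zip(universe, sig):
                if s:
                    graph.add_edge(*link)
            expected = set()
            for comp in nx.connected_components(graph):
                links = [
                    (l, f)
                    for l, s, f in zip(universe, sig, f_obs)
                    if s and l[0] in comp and l[1] in comp
                ]
                if (
                    len(comp & roi_a) >= 0.25 * len(roi_a)
                    and len(comp & roi_b) >= 0.25 * len(roi_b)
                    and len(links) >= 0.10 * len(universe)
                ):
                    expected.add(
                        (frozenset(comp), round(sum(f for _, f in links), 9))
                    )
            assert got == expected


class TestMotifPermTest:
    def test_empty_motif_list_passes_through(self, design39, atlas24, rng):
        universe = link_universe(atlas24, "FMC", "rIPL")
        y = 1 + 0.05 * rng.normal(size=(39, len(universe)))
        stats = linkwise_perm_ancova(
            y, design39, universe, n_perm=19, roi_pair=("FMC", "rIPL")
        )
        assert motif_perm_test([], stats, atlas24) == []

    def test_planted_block_reaches_minimum_corrected_p(self, design39, atlas24, rng):
        universe = link_universe(atlas24, "FMC", "rIPL")
        fmc = atlas24.roi_nodes("FMC")
        ripl = atlas24.roi_nodes("rIPL")
        planted = {
            tuple(sorted((fmc[0], ripl[0]))),
            tuple(sorted((fmc[1], ripl[0]))),
            tuple(sorted((fmc[0], ripl[1]))),
        }
        y = 1 + 0.01 * rng.normal(size=(39, len(universe)))
        bd = design39.group_indicator().astype(bool)
        for idx, link in enumerate(universe):
            if link in planted:
                y[bd, idx] += 1.0
        n_perm = 199
        stats = linkwise_perm_ancova(
            y, design39, universe, n_perm=n_perm, seed=3, roi_pair=("FMC", "rIPL")
        )
        motifs = motif_perm_test(extract_motifs(stats, atlas24), stats, atlas24)
        assert motifs
        assert motifs[0].corrected_p == pytest.approx(1.0 / (n_perm + 1))

    def test_requires_stored_permutations(self, design39, atlas24, rng):
        universe = link_universe(atlas24, "FMC", "rIPL")
        y = 1 + 0.05 * rng.normal(size=(39, len(universe)))
        stats = linkwise_perm_ancova(
            y, design39, universe, n_perm=19, keep_perms=False,
            roi_pair=("FMC", "rIPL"),
        )
        motif = Motif(roi_pair=("FMC", "rIPL"), nodes=(0,), links=(), mass=1.0)
        with pytest.raises(ValueError, match="keep_perms"):
            motif_perm_test([motif], stats, atlas24)


class TestMotifDegree:
    def motif(self, links):
        nodes = tuple(sorted({n for l in links for n in l}))
        return Motif(roi_pair=("FMC", "rIPL"), nodes=nodes,
                     links=tuple(links), mass=1.0)

    def test_single_link(self):
        mat = np.ones((4, 4))
        mat[0, 1] = mat[1, 0] = 1.2
        deg = motif_degree(self.motif([(0, 1)]), {"s1": mat})
        assert deg["s1"] == pytest.approx(1.2)

    def test_all_ones_gives_unit_degree(self):
        deg = motif_degree(self.motif([(0, 1), (2, 3)]), {"a": np.ones((4, 4))})
        assert deg["a"] == pytest.approx(1.0)

    def test_mean_of_two_links(self):
        mat = np.ones((4, 4))
        mat[0, 1] = mat[1, 0] = 0.8
        mat[2, 3] = mat[3, 2] = 1.2
        deg = motif_degree(self.motif([(0, 1), (2, 3)]), {"s": mat})
        assert deg["s"] == pytest.approx(1.0)


class TestDegreeGroupTest:
    def degrees_for(self, design, bd_vals, cn_vals):
        values = {}
        bd_iter, cn_iter = iter(bd_vals), iter(cn_vals)
        for sid, g in zip(design.subject_ids, design.groups):
            values[sid] = next(bd_iter if g == "bd" else cn_iter)
        return pd.Series(values)

    def test_identical_group_moments_give_zero_effect(self, design39):
        rng = np.random.default_rng(0)
        bd = with_moments(rng, 1.0, 0.05, 17)
        cn = with_moments(rng, 1.0, 0.05, 22)
        deg = self.degrees_for(design39, bd, cn)
        res = degree_group_test(deg, design39)
        assert res["cohen_d"] == pytest.approx(0.0, abs=1e-10)
        assert res["bd_mean"] == pytest.approx(res["control_mean"])

    def test_bonferroni_is_times_five(self, design39, rng):
        deg = self.degrees_for(
            design39, with_moments(rng, 1.05, 0.06, 17), with_moments(rng, 1.0, 0.06, 22)
        )
        res = degree_group_test(deg, design39, n_bands=5)
        assert res["p_corrected"] == pytest.approx(min(1.0, 5 * res["p_raw"]))

    def test_cohens_d_pooled_formula(self, design39, rng):
        deg = self.degrees_for(
            design39,
            with_moments(rng, 1.07, 0.07, 17),
            with_moments(rng, 0.99, 0.05, 22),
        )
        res = degree_group_test(deg, design39)
        # closed-form pooled-SD oracle on the printed-scale moments
        pooled = np.sqrt((16 * 0.07**2 + 21 * 0.05**2) / 37)
        assert res["cohen_d"] == pytest.approx(0.08 / pooled, abs=1e-9)
        assert res["cohen_d"] == pytest.approx(1.345, abs=0.01)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d(np.ones(5), np.ones(6))


class TestOneSampleTVs1:
    def test_reference_summary_example(self):
        res = one_sample_t_vs1((1.07, 0.07, 17))
        assert res["t"] == pytest.approx(4.123, abs=1e-3)
        assert res["p_two_sided"] < 1e-3

    def test_mean_one_gives_unit_p(self):
        res = one_sample_t_vs1((1.00, 0.05, 20))
        assert res["t"] == 0.0
        assert res["p_two_sided"] == 1.0

    def test_negative_direction(self):
        res = one_sample_t_vs1((0.96, 0.04, 22))
        assert res["t"] == pytest.approx(-4.690, abs=1e-3)
        assert res["p_two_sided"] == pytest.approx(1.25e-4, rel=0.01)

    def test_matches_numerical_integration_oracle(self):
        from scipy import integrate
        from scipy import stats as sps

        for summary in [(1.03, 0.06, 17), (0.95, 0.08, 22), (1.2, 0.3, 10)]:
            res = one_sample_t_vs1(summary)
            df = summary[2] - 1
            tail, _ = integrate.quad(lambda u: sps.t.pdf(u, df), abs(res["t"]), np.inf)
            assert res["p_two_sided"] == pytest.approx(2 * tail, rel=1e-8)

    def test_array_input_matches_summary_input(self, rng):
        x = with_moments(rng, 1.04, 0.05, 12)
        a = one_sample_t_vs1(x)
        b = one_sample_t_vs1((x.mean(), x.std(ddof=1), len(x)))
        assert a["t"] == pytest.approx(b["t"], rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedEffectError):
            one_sample_t_vs1((1.0, 0.0, 10))
        with pytest.raises(DesignError):
            one_sample_t_vs1((1.0, 0.1, 1))


class TestLooLogregAccuracy:
    def test_perfect_separation(self, rng):
        deg = np.r_[rng.normal(0.95, 0.005, 22), rng.normal(1.10, 0.005, 17)]
        groups = ["control"] * 22 + ["bd"] * 17
        assert loo_logreg_accuracy(deg, groups) == 1.0

    def test_constant_degree_predicts_majority(self):
        deg = np.ones(39)
        groups = ["control"] * 22 + ["bd"] * 17
        assert loo_logreg_accuracy(deg, groups) == pytest.approx(22 / 39)

    def test_null_degrees_near_chance(self, rng):
        accs = []
        groups = ["control"] * 22 + ["bd"] * 17
        for _ in range(20):
            deg = rng.normal(1.0, 0.05, 39)
            accs.append(loo_logreg_accuracy(deg, groups))
        assert 0.3 < np.mean(accs) < 0.7

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            loo_logreg_accuracy(np.ones(5), ["bd"] * 5)
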