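"""Mann-Whitney screen, BH correction, coexpression modules, adaptive
lasso pruning, bimodal fits and the mean + 2SD allocation rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matriscope import (
    adaptive_lasso_prune,
    benjamini_hochberg,
    cluster_level_genes,
    coexpression_modules,
    fit_bimodal,
    intersect_landmarks,
    mwu_screen,
    subtype_level_genes,
    two_sd_select,
)


# ------------------------------------------------------------------- BH

class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.2] * 5), 0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(benjamini_hochberg([1.0] * 4), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_monotone_in_p_and_bounded(self, pvals):
        p = np.asarray(pvals)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# ----------------------------------------------------------------- screen

def _toy_frame(x, y):
    expr = pd.DataFrame([list(x) + list(y)],
                        index=["g"],
                        columns=[f"S{i}" for i in range(len(x) + len(y))])
    ann = pd.DataFrame(
        {"subtype": ["A"] * len(x) + ["B"] * len(y)}, index=expr.columns
    )
    return expr, ann


class TestMwuScreen:
    def test_exact_small_sample_p(self):
        expr, ann = _toy_frame([1, 2], [3, 4])
        res = mwu_screen(expr, ann, {"A": 0, "B": 1}, "A")
        assert res.table.loc["g", "p"] == pytest.approx(1 / 3)

    def test_same_cluster_subtype_excluded(self, small_cohort):
        c = small_cohort
        clusters = c.annotation.groupby("subtype")["meta_cluster"].first()
        # pick a focal subtype outside the no-exclusion (largest) cluster
        res = mwu_screen(
            c.expression, c.annotation, clusters.to_dict(), "T2.a",
            no_exclusion_clusters={"NONE"},
        )
        assert "T2.b" in res.excluded_subtypes

    def test_no_exclusion_for_exempt_cluster(self, small_cohort):
        c = small_cohort
        clusters = c.annotation.groupby("subtype")["meta_cluster"].first()
        res = mwu_screen(
            c.expression, c.annotation, clusters.to_dict(), "T2.a",
            no_exclusion_clusters={clusters["T2.a"]},
        )
        assert res.excluded_subtypes == ()

    def test_empty_background_error(self):
        expr, ann = _toy_frame([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError, match="[Bb]ackground"):
            mwu_screen(expr, ann, {"A": 0, "B": 0}, "A",
                       no_exclusion_clusters={"NONE"})

    def test_rank_test_invariant_to_monotone_transform(self, small_cohort):
        c = small_cohort
        clusters = c.annotation.groupby("subtype")["meta_cluster"] \
            .first().to_dict()
        r1 = mwu_screen(c.expression, c.annotation, clusters, "T1.a")
        r2 = mwu_screen(np.exp(c.expression / 4), c.annotation, clusters,
                        "T1.a")
        assert np.allclose(r1.table["p"], r2.table["p"])

    def test_null_significant_count_near_alpha_m(self, rng):
        """Under label permutation the raw p < alpha count is ~ alpha*m."""
        m, n = 150, 120
        expr = pd.DataFrame(
            rng.normal(size=(m, n)),
            index=[f"g{i}" for i in range(m)],
            columns=[f"S{i}" for i in range(n)],
        )
        fracs = []
        for _ in range(30):
            lab = rng.permutation(["A"] * 30 + ["B"] * 90)
            ann = pd.DataFrame({"subtype": lab}, index=expr.columns)
            res = mwu_screen(expr, ann, {"A": 0, "B": 1}, "A",
                             no_exclusion_clusters={0, 1})
            fracs.append((res.table["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02


# ------------------------------------------------------------ coexpression

def _block_expression(rng, n_samples=60, block=8, noise=12, rho=0.9):
    """Two orthogonal co-expressed blocks plus independent noise genes."""
    z1 = rng.normal(size=n_samples)
    z2 = rng.normal(size=n_samples)
    rows, names = [], []
    lam = np.sqrt(rho)
    for b, z in ((1, z1), (2, z2)):
        for i in range(block):
            rows.append(lam * z + np.sqrt(1 - rho) * rng.normal(size=n_samples))
            names.append(f"B{b}_{i}")
    for i in range(noise):
        rows.append(rng.normal(size=n_samples))
        names.append(f"N{i}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"S{i}" for i in range(n_samples)])


class TestCoexpressionModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr = _block_expression(rng)
        mods = coexpression_modules(expr)
        mem = mods.membership
        b1 = set(mem[mem.index.str.startswith("B1_")])
        b2 = set(mem[mem.index.str.startswith("B2_")])
        assert len(b1) == 1 and len(b2) == 1 and b1 != b2
        assert 0 not in b1 | b2

    def test_duplicated_gene_same_module(self, rng):
        expr = _block_expression(rng)
        expr.loc["B1_dup"] = expr.loc["B1_0"] + rng.normal(
            scale=1e-3, size=expr.shape[1]
        )
        mods = coexpression_modules(expr)
        assert mods.membership["B1_dup"] == mods.membership["B1_0"]

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = _block_expression(rng)
        expr.loc["CONST"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            mods = coexpression_modules(expr)
        assert "CONST" not in mods.membership.index

    def test_null_modules_not_subtype_associated(self):
        """Independent noise genes: no module should associate with a random
        subtype indicator (q < 0.05) in >= 18 of 20 seeds."""
        clean = 0
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            expr = pd.DataFrame(
                r.normal(size=(30, 60)),
                index=[f"g{i}" for i in range(30)],
                columns=[f"S{i}" for i in range(60)],
            )
            ann = pd.DataFrame(
                {"subtype": r.permutation(["A"] * 15 + ["B"] * 45)},
                index=expr.columns,
            )
            mods = coexpression_modules(expr, min_module_size=3)
            genes = mods.genes_in_associated_modules(ann, "A", alpha=0.05)
            clean += int(len(genes) == 0)
        assert clean >= 18

    def test_cluster_level_intersection_semantics(self, rng):
        expr = _block_expression(rng)
        ann = pd.DataFrame(
            {"subtype": ["A"] * 30 + ["B"] * 30}, index=expr.columns
        )
        # make block 1 track subtype A so its module associates
        expr.loc[expr.index.str.startswith("B1_"), ann["subtype"] == "A"] += 3.0
        mods = coexpression_modules(expr)
        screen = mwu_screen(expr, ann, {"A": 0, "B": 1}, "A",
                            no_exclusion_clusters={0, 1})
        genes = cluster_level_genes(screen, mods, ann, "A")
        assert genes  # the shifted block passes both
        assert all(g.startswith("B1_") for g in genes)
        # a screen-significant gene outside an associated module is excluded
        sig_only = screen.significant - set(
            mods.membership.index[mods.membership > 0]
        )
        assert not (genes & sig_only)


# ---------------------------------------------------------- adaptive lasso

class TestAdaptiveLasso:
    def _frame(self, rng, n=200, p_noise=20, effect=3.0):
        y = np.array([1] * (n // 4) + [0] * (n - n // 4))
        rows = {"signal": y * effect + rng.normal(size=n)}
        for i in range(p_noise):
            rows[f"noise{i}"] = rng.normal(size=n)
        return pd.DataFrame(rows).T, y

    def test_planted_gene_selected_few_false_positives(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr, y = self._frame(rng)
            sel = adaptive_lasso_prune(expr, y, folds=5, random_state=seed)
            ok += int("signal" in sel and len(sel - {"signal"}) <= 2)
        assert ok >= 17

    def test_shuffled_labels_select_nothing(self):
        counts = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            expr, y = self._frame(rng, effect=0.0)
            sel = adaptive_lasso_prune(
                expr, rng.permutation(y), folds=5, random_state=seed
            )
            counts.append(len(sel))
        assert np.median(counts) == 0

    def test_zero_variance_gene_never_selected(self, rng):
        expr, y = self._frame(rng)
        expr.loc["flat"] = 5.0
        sel = adaptive_lasso_prune(expr, y, folds=5, random_state=0)
        assert "flat" not in sel

    def test_single_candidate_passes_untested(self, rng):
        expr, y = self._frame(rng)
        sel = adaptive_lasso_prune(expr.iloc[[0]], y)
        assert sel == {"signal"}

    def test_empty_candidates_empty_selection(self, rng):
        expr, y = self._frame(rng)
        assert adaptive_lasso_prune(expr.iloc[:0], y) == set()


# -------------------------------------------------------------- bimodality

class TestBimodalFit:
    def test_recovers_upper_component_mean(self, rng):
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
        fit = fit_bimodal(x)
        assert abs(fit.means[1] - 6.0) < 0.3
        assert fit.means[0] <= fit.means[1]

    def test_loglik_non_decreasing(self, rng):
        from matriscope.estimators import BimodalGaussianMixture

        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 2, 100)])
        est = BimodalGaussianMixture().fit(x)
        assert (np.diff(est.log_likelihood_path_) >= -1e-9).all()

    def test_unimodal_converges_without_error(self, rng):
        # overlapping components are an acceptable fit, not an error
        fit = fit_bimodal(rng.normal(size=200))
        assert fit.converged
        assert np.isfinite(fit.separation)
        assert fit.means[0] <= fit.means[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_bimodal(np.ones(50))

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            fit_bimodal(rng.normal(size=5))


# ---------------------------------------------------------------- 2SD rule

def _expr_ann(values_by_subtype):
    cols, labs, vals = [], [], []
    i = 0
    for st_name, vs in values_by_subtype.items():
        for v in vs:
            cols.append(f"S{i}")
            labs.append(st_name)
            vals.append(v)
            i += 1
    expr = pd.DataFrame([vals], index=["g"], columns=cols)
    ann = pd.DataFrame({"subtype": labs}, index=cols)
    return expr, ann


class TestTwoSdRule:
    def test_boundary_exactly_mean_plus_2sd_selected(self):
        # cohort: subtype A constant at m + 2s by construction
        rng = np.random.default_rng(0)
        bg = rng.normal(0, 1, 200)
        expr, ann = _expr_ann({"B": bg})
        m, s = bg.mean(), bg.std()
        # append subtype A samples all exactly at the cutoff of the *final*
        # cohort: solve by iteration
        target = m + 2 * s
        for _ in range(200):
            full = np.concatenate([bg, [target] * 20])
            target = full.mean() + 2 * full.std()
        expr, ann = _expr_ann({"B": bg, "A": [target] * 20})
        assert two_sd_select("g", "A", expr, ann, min_samples=2)

    def test_below_cutoff_not_selected(self, rng):
        expr, ann = _expr_ann({"B": rng.normal(0, 1, 100),
                               "A": rng.normal(1.0, 1, 20)})
        assert not two_sd_select("g", "A", expr, ann, min_samples=2)

    def test_constant_gene_degenerate_rule(self):
        expr, ann = _expr_ann({"B": [5.0] * 50, "A": [5.0] * 20})
        assert not two_sd_select("g", "A", expr, ann, min_samples=2)

    def test_affine_equivariance(self, rng):
        bg = rng.normal(8, 2, 100)
        sub = rng.normal(16, 1, 20)
        expr, ann = _expr_ann({"B": bg, "A": sub})
        direct = two_sd_select("g", "A", expr, ann, min_samples=2)
        scaled = two_sd_select("g", "A", 3.0 * expr + 7.0, ann, min_samples=2)
        assert direct == scaled

    def test_small_subtype_ineligible(self, rng):
        expr, ann = _expr_ann({"B": rng.normal(0, 1, 100),
                               "A": [10.0] * 5})
        assert not two_sd_select("g", "A", expr, ann, min_samples=10)

    def test_vectorised_matches_scalar(self, small_cohort):
        c = small_cohort
        st_name = "T1.a"
        fast = subtype_level_genes(c.expression, c.annotation, st_name)
        slow = {
            g
            for g in c.expression.index
            if two_sd_select(g, st_name, c.expression, c.annotation)
        }
        assert fast == slow


# ------------------------------------------------------------ intersection

class TestIntersectLandmarks:
    def test_disjoint_sets_empty(self):
        ls = intersect_landmarks({"A": {"g1"}}, {"A": {"g2"}})
        assert ls.landmarks == {}

    def test_identical_sets_pass_through(self):
        ls = intersect_landmarks({"A": {"g1", "g2"}}, {"A": {"g1", "g2"}})
        assert ls.landmarks == {"A": {"g1", "g2"}}

    def test_provenance_flags_retained(self):
        ls = intersect_landmarks({"A": {"g1"}}, {"A": {"g1", "g2"}})
        t = ls.table.set_index("gene")
        assert bool(t.loc["g1", "cluster_pass"]) and bool(
            t.loc["g1", "subtype_pass"]
        )
        assert not t.loc["g2", "cluster_pass"]
        assert ls.pairs() == {("A", "g1")}
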