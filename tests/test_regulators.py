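"""Design assembly, eligibility, sPCR and RFR selection behavior."""

import numpy as np
import pandas as pd
import pytest

from matriscope import (
    RegulatorLayers,
    Triplet,
    assemble_design,
    eligibility_filter,
    extract_triplets,
    rfr_fit,
    spcr_fit,
)

FAST_RF = dict(folds=3, n_estimators=60, cv_n_estimators=25,
               n_permutation_repeats=1)


def _design(rng, n=50, p=15):
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"tf:TF{i:03d}" for i in range(p)],
        index=[f"S{i}" for i in range(n)],
    )
    return X


# -------------------------------------------------------------- assembly

class TestAssembleDesign:
    def test_constant_column_dropped(self, small_cohort):
        c = small_cohort
        layers = {k: v.copy() for k, v in c.layers.layers.items()}
        layers["tf"].loc["TF001"] = 1.0
        st, g = sorted(c.truth.markers)[0]
        X = assemble_design(RegulatorLayers(layers), c.annotation, st, g)
        assert "tf:TF001" not in X.columns

    def test_tf_map_restricts_regulators(self, small_cohort):
        c = small_cohort
        st, g = sorted(c.truth.markers)[0]
        other = sorted({x for _, x in c.truth.markers} - {g})[0]
        tf_map = pd.DataFrame(
            {"regulator": ["TF001"], "target": [g]}
        )
        Xg = assemble_design(c.layers, c.annotation, st, g, tf_targets=tf_map)
        Xo = assemble_design(c.layers, c.annotation, st, other,
                             tf_targets=tf_map)
        assert [c_ for c_ in Xg.columns if c_.startswith("tf:")] == ["tf:TF001"]
        assert not [c_ for c_ in Xo.columns if c_.startswith("tf:")]

    def test_width_accounting(self, small_cohort):
        c = small_cohort
        st, g = sorted(c.truth.markers)[0]
        X = assemble_design(c.layers, c.annotation, st, g, standardize=False)
        expected = 0
        samples = c.annotation.index[c.annotation["subtype"] == st]
        for name, frame in c.layers:
            sub = frame.loc[:, samples]
            if name in ("cna", "methylation", "mutation"):
                sub = sub.loc[[g]]
            expected += int((sub.std(axis=1) > 0).sum())
        assert X.shape[1] == expected

    def test_continuous_columns_standardized(self, small_cohort):
        c = small_cohort
        st, g = sorted(c.truth.markers)[0]
        X = assemble_design(c.layers, c.annotation, st, g)
        tf_cols = [c_ for c_ in X.columns if c_.startswith("tf:")]
        assert np.allclose(X[tf_cols].mean(), 0, atol=1e-9)
        assert np.allclose(X[tf_cols].std(), 1, atol=1e-9)

    def test_standardization_absorbs_affine_rescaling(self, small_cohort):
        c = small_cohort
        st, g = sorted(c.truth.markers)[0]
        X1 = assemble_design(c.layers, c.annotation, st, g)
        layers = {k: v.copy() for k, v in c.layers.layers.items()}
        layers["tf"] = layers["tf"] * 5.0 + 2.0
        X2 = assemble_design(RegulatorLayers(layers), c.annotation, st, g)
        tf_cols = [c_ for c_ in X1.columns if c_.startswith("tf:")]
        assert np.allclose(X1[tf_cols], X2[tf_cols])


# ------------------------------------------------------------ eligibility

class TestEligibility:
    def _setup(self, n_sub):
        samples = [f"S{i}" for i in range(n_sub + 30)]
        ann = pd.DataFrame(
            {"subtype": ["A"] * n_sub + ["B"] * 30}, index=samples
        )
        expr = pd.DataFrame(
            np.ones((1, len(samples))), index=["g"], columns=samples
        )
        return expr, ann

    def test_nine_patients_dropped_ten_kept(self):
        for n, expected in ((9, 0), (10, 1)):
            expr, ann = self._setup(n)
            tasks = eligibility_filter(ann, expr, {"A": {"g"}})
            assert len(tasks) == expected

    def test_nonzero_count_boundary(self):
        expr, ann = self._setup(12)
        vals = np.zeros(42)
        vals[:10] = 1.0  # exactly 10 non-zero within subtype A
        expr.loc["g"] = vals
        assert eligibility_filter(ann, expr, {"A": {"g"}}) == [("A", "g")]
        vals[9] = 0.0
        expr.loc["g"] = vals
        assert eligibility_filter(ann, expr, {"A": {"g"}}) == []

    def test_empty_landmarks_no_tasks(self):
        expr, ann = self._setup(12)
        assert eligibility_filter(ann, expr, {}) == []


# ------------------------------------------------------------------ sPCR

class TestSpcr:
    def test_perfect_signal_selected_dominant(self, rng):
        X = _design(rng)
        y = X["tf:TF003"].to_numpy()
        sel = spcr_fit(y, X, random_state=0)
        assert "tf:TF003" in sel
        assert abs(sel["tf:TF003"]) == max(abs(v) for v in sel.values())

    def test_noise_selects_nothing_median(self):
        counts = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = _design(rng)
            y = rng.normal(size=len(X))
            counts.append(len(spcr_fit(y, X, random_state=seed)))
        assert np.median(counts) == 0

    def test_planted_link_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = _design(rng)
            y = X["tf:TF005"].to_numpy() + rng.normal(scale=0.5, size=len(X))
            hits += int("tf:TF005" in spcr_fit(y, X, random_state=seed))
        assert hits >= 24

    def test_column_order_invariance(self, rng):
        X = _design(rng)
        y = X["tf:TF005"].to_numpy() + rng.normal(scale=0.5, size=len(X))
        s1 = spcr_fit(y, X, random_state=0)
        s2 = spcr_fit(y, X[list(X.columns[::-1])], random_state=0)
        assert set(s1) == set(s2)


# ------------------------------------------------------------------- RFR

class TestRfr:
    def test_binary_step_ranked_first(self, rng):
        X = _design(rng, n=60)
        X["mutation:G"] = (rng.random(60) < 0.4).astype(float)
        y = X["mutation:G"].to_numpy() * 3 + rng.normal(scale=0.3, size=60)
        sel = rfr_fit(y, X, random_state=0, **FAST_RF)
        assert "mutation:G" in sel
        assert sel["mutation:G"] == max(sel.values())

    def test_all_noise_selects_nothing(self):
        clean = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = _design(rng, n=60)
            y = rng.normal(size=60)
            clean += int(len(rfr_fit(y, X, random_state=seed, **FAST_RF)) == 0)
        assert clean >= 27

    def test_nonlinear_threshold_link_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = _design(rng, n=60)
            y = (X["tf:TF002"].to_numpy() > 0) * 2.0 + rng.normal(
                scale=0.5, size=60
            )
            hits += int(
                "tf:TF002" in rfr_fit(y, X, random_state=seed, **FAST_RF)
            )
        assert hits >= 24


class TestMethodComplementarity:
    """The two regressors specialise: the linear method on linear links,
    the forest on symmetric threshold links invisible to correlation."""

    def test_linear_vs_threshold_recall_ordering(self):
        spcr_lin = rfr_lin = spcr_thr = rfr_thr = 0
        n = 60
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _design(rng, n=n)
            x = X["tf:TF001"].to_numpy()
            y_lin = x + rng.normal(scale=0.5, size=n)
            y_thr = 2.0 * (np.abs(x) > 1.0) + rng.normal(scale=0.5, size=n)
            spcr_lin += "tf:TF001" in spcr_fit(y_lin, X, random_state=seed)
            rfr_lin += "tf:TF001" in rfr_fit(y_lin, X, random_state=seed,
                                             **FAST_RF)
            spcr_thr += "tf:TF001" in spcr_fit(y_thr, X, random_state=seed)
            rfr_thr += "tf:TF001" in rfr_fit(y_thr, X, random_state=seed,
                                             **FAST_RF)
        assert spcr_lin >= rfr_lin
        assert rfr_thr >= spcr_thr
        assert rfr_thr > rfr_lin - 20  # forest actually sees threshold links
        assert rfr_thr >= 10


# ---------------------------------------------------------------- triplets

class TestExtractTriplets:
    def test_identical_selections_tagged_both(self):
        s = {("A", "g"): {"tf:TF001": 1.0}}
        r = {("A", "g"): {"tf:TF001": 0.5}}
        t = extract_triplets(s, r)
        assert list(t["source"]) == ["both"]
        assert t.loc[0, "score"] == 1.0  # linear coefficient preferred

    def test_disjoint_selections_never_both(self):
        s = {("A", "g"): {"tf:TF001": 1.0}}
        r = {("A", "g"): {"tf:TF002": 0.5}}
        t = extract_triplets(s, r)
        assert set(t["source"]) == {"spcr", "rfr"}

    def test_stable_ordering(self):
        s = {("B", "g2"): {"tf:TF002": 1.0}, ("A", "g1"): {"cna:g1": 1.0}}
        t = extract_triplets(s, {})
        assert list(t["subtype"]) == ["A", "B"]
        assert list(t["layer"]) == ["cna", "tf"]

    def test_invalid_triplet_rejected(self):
        with pytest.raises(ValueError):
            Triplet("A", "g", "r", "tf", "neither", 1.0)
        with pytest.raises(ValueError):
            Triplet("A", "g", "r", "tf", "spcr", float("nan"))
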