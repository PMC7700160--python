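"""Scikit-learn-style estimators behind the pipeline's model-shaped steps.

Four primitives live here:

* :class:`BimodalGaussianMixture` — two-component univariate normal
  mixture fitted by EM, used for the subtype-level bimodality diagnostic.
* :class:`AdaptiveLassoLogistic` — two-stage adaptive-lasso logistic
  classifier (ridge pilot, weighted L1 path, CV-chosen penalty) used to
  prune cluster-level candidate genes.
* :class:`SparseComponentRegressor` — supervised sparse-component
  regression: components are soft-supported covariance directions
  estimated jointly with the response, the component count chosen by
  cross-validation (zero components allowed, so pure noise selects
  nothing).
* :class:`ShadowForestSelector` — random-forest regression with
  permutation importances calibrated against an equal-width block of
  permuted shadow features.

All follow the fit / fitted-attribute (trailing underscore) convention and
compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted


class BimodalGaussianMixture(BaseEstimator):
    """Two-component univariate Gaussian mixture via EM.

    Components are ordered ``means_[0] <= means_[1]``.  Initialization is
    a deterministic two-means split of the sorted values; convergence when
    the log-likelihood gain drops below ``tol`` or after ``max_iter``
    iterations.  The log-likelihood path is non-decreasing (EM property).

    Parameters
    ----------
    tol : float
        Absolute log-likelihood gain below which EM stops.
    max_iter : int
        Iteration cap.
    min_samples : int
        Minimum number of finite observations required to fit.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000,
                 min_samples: int = 10):
        self.tol = tol
        self.max_iter = max_iter
        self.min_samples = min_samples

    def fit(self, X, y=None):
        x = np.asarray(X, float).ravel()
        x = x[np.isfinite(x)]
        if x.size < self.min_samples:
            raise ValueError(
                f"need >= {self.min_samples} finite values, got {x.size}"
            )
        if x.std() == 0:
            raise ValueError("zero-variance input: no bimodal fit possible")
        # deterministic 2-means on sorted values: split at the midpoint
        xs = np.sort(x)
        split = xs.searchsorted(0.5 * (xs[0] + xs[-1]))
        split = min(max(split, 1), x.size - 1)
        mu = np.array([xs[:split].mean(), xs[split:].mean()])
        sd = np.array([max(xs[:split].std(), 1e-3),
                       max(xs[split:].std(), 1e-3)])
        lam = np.array([split / x.size, 1 - split / x.size])

        path = []
        prev = -np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            # E step
            logp = (
                np.log(lam)[:, None]
                - 0.5 * np.log(2 * np.pi * sd[:, None] ** 2)
                - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
            )
            m = logp.max(axis=0)
            ll = float((m + np.log(np.exp(logp - m).sum(axis=0))).sum())
            path.append(ll)
            if ll - prev < self.tol and n_iter > 1:
                converged = True
                break
            prev = ll
            resp = np.exp(logp - m) / np.exp(logp - m).sum(axis=0)
            # M step
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-10)
            mu = (resp * x).sum(axis=1) / nk
            var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
            sd = np.sqrt(np.maximum(var, 1e-6))
            lam = nk / x.size

        order = np.argsort(mu)
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.weights_ = lam[order]
        self.log_likelihood_ = path[-1]
        self.log_likelihood_path_ = np.asarray(path)
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "means_")
        x = np.asarray(X, float).ravel()
        logp = (
            np.log(self.weights_)[:, None]
            - 0.5 * np.log(2 * np.pi * self.sds_[:, None] ** 2)
            - 0.5 * ((x[None, :] - self.means_[:, None]) / self.sds_[:, None]) ** 2
        )
        m = logp.max(axis=0)
        p = np.exp(logp - m)
        return (p / p.sum(axis=0)).T

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


class AdaptiveLassoLogistic(ClassifierMixin, BaseEstimator):
    """Adaptive-lasso logistic regression for feature pruning.

    A ridge pilot fit provides coefficients ``b``; penalty weights
    ``1/|b|`` re-scale the columns and an L1 logistic path is
    cross-validated on deviance.  The strongest penalty within one
    standard error of the CV minimum is kept (one-SE rule), so shuffled
    labels select nothing.  Features with a non-zero (back-transformed)
    coefficient form ``support_``.
    """

    def __init__(self, cv: int = 10, Cs: int = 10, pilot_C: float = 1.0,
                 random_state: int | None = None):
        self.cv = cv
        self.Cs = Cs
        self.pilot_C = pilot_C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        scale = X.std(axis=0)
        informative = scale > 0
        mean = X.mean(axis=0)
        Xs = np.zeros_like(X)
        Xs[:, informative] = (
            (X[:, informative] - mean[informative]) / scale[informative]
        )
        pilot = LogisticRegression(
            penalty="l2", C=self.pilot_C, max_iter=2000
        ).fit(Xs, y)
        w = np.abs(pilot.coef_.ravel())
        active = informative & (w > 1e-12)
        self.pilot_coef_ = pilot.coef_.ravel()
        coef = np.zeros(X.shape[1])
        if active.any():
            Xw = Xs[:, active] * w[active]  # column scaling = 1/w penalty
            n_splits = min(self.cv, int(np.bincount(y.astype(int)).min()))
            n_splits = max(n_splits, 2)
            cvs = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.random_state
            )
            grid = np.logspace(-2.5, 1.5, self.Cs)
            # column 0 is the intercept-only null model (the path's limit)
            loss = np.zeros((n_splits, len(grid) + 1))
            from sklearn.metrics import log_loss

            for fi, (tr, te) in enumerate(cvs.split(Xw, y)):
                base = np.full(len(te), y[tr].mean())
                loss[fi, 0] = log_loss(y[te], base, labels=[0, 1])
                for ci, C in enumerate(grid, start=1):
                    clf = LogisticRegression(
                        penalty="l1", solver="liblinear", C=C, max_iter=2000,
                        random_state=self.random_state,
                    ).fit(Xw[tr], y[tr])
                    loss[fi, ci] = log_loss(
                        y[te], clf.predict_proba(Xw[te])[:, 1], labels=[0, 1]
                    )
            mean = loss.mean(axis=0)
            best = int(np.argmin(mean))
            se = loss[:, best].std(ddof=1) / np.sqrt(n_splits)
            # one-SE rule: simplest model whose deviance stays within one
            # SE of the minimum; index 0 selects nothing
            pick = int(np.flatnonzero(mean <= mean[best] + se)[0])
            self.cv_deviance_ = mean
            if pick > 0:
                c_sel = grid[pick - 1]
                final = LogisticRegression(
                    penalty="l1", solver="liblinear", C=float(c_sel),
                    max_iter=5000, random_state=self.random_state,
                ).fit(Xw, y)
                coef[active] = final.coef_.ravel() * w[active]
                self.C_ = float(c_sel)
        self.coef_ = coef
        self.support_ = np.abs(coef) > 1e-10
        self.classes_ = np.unique(y)
        self._mean = mean
        self._scale = np.where(scale > 0, scale, 1.0)
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Xs = (np.asarray(X, float) - self._mean) / self._scale
        return Xs @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class SparseComponentRegressor(RegressorMixin, BaseEstimator):
    """Supervised sparse principal-component regression.

    Each component direction is the response-covariance vector restricted
    to its dominant support (columns whose absolute covariance with the
    current residual reaches ``threshold_frac`` of the maximum), i.e. the
    loadings are estimated jointly with the regression rather than from
    the design alone.  Both the response and the design are deflated
    between components.  The component count ``k`` is chosen over
    ``0..n_components_max`` by K-fold CV of the mean squared error — the
    zero-component (intercept-only) model competes, so an uninformative
    design selects no regressors.  A regressor is selected iff it carries
    a non-zero loading on a retained component.
    """

    def __init__(self, n_components_max: int = 5, threshold_frac: float = 0.5,
                 cv: int = 5, select_alpha: float = 0.01,
                 random_state: int | None = None):
        self.n_components_max = n_components_max
        self.threshold_frac = threshold_frac
        self.cv = cv
        self.select_alpha = select_alpha
        self.random_state = random_state

    def _components(self, X, y, k_max):
        """Greedy supervised sparse directions with deflation."""
        n, p = X.shape
        Xr = X.copy()
        yr = y - y.mean()
        comps = []
        for _ in range(k_max):
            c = Xr.T @ yr / n
            amax = np.abs(c).max()
            if amax < 1e-12:
                break
            support = np.abs(c) >= self.threshold_frac * amax
            w = np.where(support, c, 0.0)
            w /= np.linalg.norm(w)
            t = Xr @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            beta = float(t @ yr) / tt
            comps.append((w, beta))
            # deflate
            yr = yr - beta * t
            Xr = Xr - np.outer(t, t @ Xr) / tt
        return comps

    def _prune_support(self, Xs, y, support):
        """OLS refit on the supported columns; keep coefficients passing a
        Benjamini-Hochberg check at ``select_alpha`` across the support
        (calibrates the expected false-selection fraction)."""
        from scipy import stats as _st
        from statsmodels.stats.multitest import multipletests

        m = len(support)
        n = len(y)
        if m == 0 or n - m - 1 <= 0:
            return support
        A = np.column_stack([np.ones(n), Xs[:, support]])
        coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        dof = n - A.shape[1]
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.maximum(np.diag(cov), 1e-30))
        tvals = coef / se
        pvals = 2 * _st.t.sf(np.abs(tvals), dof)
        qvals = multipletests(pvals[1:], method="fdr_bh")[1]
        return support[qvals < self.select_alpha]

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd
        k_max = min(self.n_components_max, p, max(n - 2, 1))

        n_splits = min(self.cv, n)
        kf = KFold(n_splits=n_splits, shuffle=True,
                   random_state=self.random_state)
        fold_mse = np.zeros((n_splits, k_max + 1))
        for fi, (tr, te) in enumerate(kf.split(Xs)):
            ytr, yte = y[tr], y[te]
            fold_mse[fi, 0] = ((yte - ytr.mean()) ** 2).mean()
            comps = self._components(Xs[tr], ytr, k_max)
            pred = np.full(len(te), ytr.mean())
            Xte = Xs[te].copy()
            Xtr = Xs[tr].copy()
            for k, (w, beta) in enumerate(comps, start=1):
                t_tr = Xtr @ w
                t_te = Xte @ w
                pred = pred + beta * t_te
                fold_mse[fi, k] = ((yte - pred) ** 2).mean()
                tt = float(t_tr @ t_tr)
                proj = (t_tr @ Xtr) / tt
                Xtr = Xtr - np.outer(t_tr, proj)
                Xte = Xte - np.outer(t_te, proj)
            for k in range(len(comps) + 1, k_max + 1):
                fold_mse[fi, k] = fold_mse[fi, len(comps)]
        self.cv_mse_ = fold_mse.mean(axis=0)
        # one-SE rule: smallest k within one standard error of the minimum
        k_min = int(np.argmin(self.cv_mse_))
        se = fold_mse[:, k_min].std(ddof=1) / np.sqrt(n_splits) \
            if n_splits > 1 else 0.0
        self.n_components_ = int(
            np.flatnonzero(self.cv_mse_ <= self.cv_mse_[k_min] + se)[0]
        )

        self.components_ = self._components(Xs, y, self.n_components_)
        coef = np.zeros(p)
        for w, beta in self.components_:
            coef += beta * w
        self.feature_coef_ = coef / sd  # back on the original scale
        support = np.flatnonzero(
            np.any([w != 0 for w, _ in self.components_], axis=0)
        ) if self.components_ else np.array([], dtype=int)
        # debias: OLS on the supported columns; keep individually
        # informative regressors (Wald p < select_alpha)
        self.selected_idx_ = self._prune_support(Xs, y, support)
        self.intercept_ = float(y.mean() - (X @ self.feature_coef_).mean()) \
            if self.components_ else float(y.mean())
        self._mu, self._sd = mu, sd
        return self

    def predict(self, X):
        check_is_fitted(self, "feature_coef_")
        return np.asarray(X, float) @ self.feature_coef_ + self.intercept_


class ShadowForestSelector(RegressorMixin, BaseEstimator):
    """Random-forest regressor with shadow-calibrated feature selection.

    The design is augmented with an equal-width block of shadow features
    (each original column independently permuted); a forest is fitted on
    the augmented design and permutation importances (mean increase in MSE
    over ``n_permutation_repeats`` shuffles) are computed for every
    column.  A real feature is selected when its importance strictly
    exceeds the maximum shadow importance *and* reaches
    ``importance_floor_frac`` of the largest real importance.  Tasks whose
    ``cv``-fold CV R^2 is <= 0 select nothing.
    """

    def __init__(self, n_estimators: int = 500, cv: int = 10,
                 cv_n_estimators: int = 100, n_permutation_repeats: int = 2,
                 importance_floor_frac: float = 0.1,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.cv = cv
        self.cv_n_estimators = cv_n_estimators
        self.n_permutation_repeats = n_permutation_repeats
        self.importance_floor_frac = importance_floor_frac
        self.random_state = random_state

    def _permutation_importance(self, rf, X, y, rng):
        """Batched permutation importance: one predict call per repeat."""
        n, p = X.shape
        base = float(np.mean((rf.predict(X) - y) ** 2))
        imp = np.zeros(p)
        for _ in range(self.n_permutation_repeats):
            big = np.repeat(X[None, :, :], p, axis=0)
            for j in range(p):
                big[j, :, j] = X[rng.permutation(n), j]
            pred = rf.predict(big.reshape(p * n, p))
            mse = np.mean(
                (pred.reshape(p, n) - y[None, :]) ** 2, axis=1
            )
            imp += mse - base
        return imp / self.n_permutation_repeats

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)

        # cross-validated R^2 gate
        n_splits = min(self.cv, n)
        kf = KFold(n_splits=n_splits, shuffle=True,
                   random_state=self.random_state)
        sse = sst = 0.0
        for tr, te in kf.split(X):
            rf = RandomForestRegressor(
                n_estimators=self.cv_n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[tr], y[tr])
            sse += ((y[te] - rf.predict(X[te])) ** 2).sum()
            sst += ((y[te] - y[tr].mean()) ** 2).sum()
        self.cv_r2_ = 1.0 - sse / sst if sst > 0 else 0.0

        shadows = np.column_stack(
            [X[rng.permutation(n), j] for j in range(p)]
        )
        X_aug = np.hstack([X, shadows])
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X_aug, y)
        imp_all = self._permutation_importance(self.forest_, X_aug, y, rng)
        self.importances_ = imp_all[:p]
        self.shadow_importances_ = imp_all[p:]
        shadow_max = self.shadow_importances_.max() if p else 0.0
        top = self.importances_.max() if p else 0.0
        if self.cv_r2_ <= 0 or top <= 0:
            self.selected_idx_ = np.array([], dtype=int)
        else:
            keep = (self.importances_ > shadow_max) & (
                self.importances_ >= self.importance_floor_frac * top
            )
            self.selected_idx_ = np.flatnonzero(keep)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_idx_] = True
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, float)
        pad = np.zeros_like(X)
        return self.forest_.predict(np.hstack([X, pad]))

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
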