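"""Shared variability: single-factor Factor Analysis of trial-to-trial
spike-count covariance, leave-neuron-out cross-validation of the latent
dimensionality, and shared-variance size tuning.

The model for the count vector x on one trial is

    x = mu + Lambda z + eps,   z ~ N(0, I_q),  eps ~ N(0, Psi)  (Psi diagonal)

so the covariance is Lambda Lambda' + Psi.  The per-unit *shared variance* is
the diagonal of Lambda Lambda' (variability common to the population) and
Psi holds the *private* variances.  Fitting is EM on the sample covariance;
the log-likelihood is monotone non-decreasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .datamodel import (FIG_AVG_WINDOW_MS, LAYERS, TrialSpikeData,
                        count_in_window)
from .tuning import DoubleRoGParams, fit_double_rog

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "CVReport",
    "fit_factor_model",
    "shared_variance",
    "cv_dimensionality",
    "shared_variance_size_tuning",
    "FA_WINDOW_MS",
    "FA_BASELINE_WINDOW_MS",
]

#: 300 ms count window for factor analysis, placed inside the stimulus epoch
FA_WINDOW_MS = FIG_AVG_WINDOW_MS  # (50, 350)
#: symmetric 300 ms window inside the 400 ms pre-stimulus baseline
FA_BASELINE_WINDOW_MS = (-350.0, -50.0)
PSI_FLOOR = 1e-6


@dataclass
class FactorModel:
    loadings: np.ndarray       # (units, q)
    private_var: np.ndarray    # (units,)
    mean: np.ndarray           # (units,)
    log_likelihood: float
    ll_history: np.ndarray
    n_trials: int
    converged: bool

    @property
    def n_units(self) -> int:
        return self.loadings.shape[0]

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    def model_cov(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.private_var)


@dataclass
class CVReport:
    q_list: list[int]
    rmse_mean: np.ndarray          # per q, averaged over folds
    rmse_by_fold: np.ndarray       # (q, folds)
    chosen_q: int
    folds: int = 5
    notes: list[str] = field(default_factory=list)


def _ll_gauss(S: np.ndarray, C: np.ndarray, n: int) -> float:
    """Gaussian log-likelihood of sample scatter S under model covariance C."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(np.linalg.solve(C, S)))


def _ll_from_chol(S: np.ndarray, cho, n: int) -> float:
    p = S.shape[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    tr = float(np.trace(sla.cho_solve(cho, S)))
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + tr)


def fit_factor_model(counts, q: int = 1, max_iter: int = 5000, tol: float = 1e-8,
                     seed: int | None = 0, prune: bool = False) -> FactorModel:
    """EM fit of a q-factor model to per-trial counts (trials x units).

    Private variances are floored at 1e-6 to prevent Heywood collapse;
    iteration stops when the log-likelihood gain per trial falls below
    ``tol``.  Deterministic given ``seed`` (loading initialisation).

    When the data carry no shared structure the likelihood is nearly flat
    along a ridge where one unit's variance is split arbitrarily between its
    loading and its private variance, which can inflate the apparent shared
    variance of that unit.  ``prune=True`` zeros a unit's loading row (moving
    its variance into Psi) whenever the likelihood cost is within what
    fitting the unit's (p-1) noisy covariances would earn by chance (a
    likelihood-ratio check at the 0.999 level).  This is useful for
    identification analyses at large trial counts; it is off by default
    because at small trial counts genuinely shared but weak structure is
    statistically indistinguishable from the ridge and would be removed.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be 2-D (trials, units)")
    n, p = X.shape
    if p < 2:
        raise ValueError("factor analysis needs >= 2 units (one unit is unidentifiable)")
    if n <= p:
        raise ValueError(f"need more trials ({n}) than units ({p})")
    mu = X.mean(axis=0)
    Xc = X - mu
    S = (Xc.T @ Xc) / n
    total_var = np.diag(S).copy()
    if np.all(total_var < 1e-12):
        raise ValueError("singular covariance: all units have zero variance")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(np.maximum(total_var, PSI_FLOOR))
    L = rng.standard_normal((p, q)) * (scale[:, None] / np.sqrt(2 * q))
    Psi = np.maximum(total_var / 2.0, PSI_FLOOR)

    ll_prev = -np.inf
    ll_hist = []
    converged = False
    eye_q = np.eye(q)
    for _ in range(max_iter):
        C = L @ L.T + np.diag(Psi)
        cho = sla.cho_factor(C, lower=True)
        ll = _ll_from_chol(S, cho, n)
        ll_hist.append(ll)
        if ll - ll_prev < tol * n and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # E-step via beta = L' C^-1 (q x p), then M-step
        beta = sla.cho_solve(cho, L).T
        SB = S @ beta.T                      # p x q
        Ezz = eye_q - beta @ L + beta @ SB   # q x q
        L = SB @ np.linalg.inv(Ezz)
        Psi = np.maximum(np.diag(S) - np.einsum("ij,ij->i", L, SB), PSI_FLOOR)
    C = L @ L.T + np.diag(Psi)
    ll = _ll_gauss(S, C, n)
    if prune:
        from scipy.stats import chi2

        thresh = 0.5 * chi2.ppf(0.999, df=max(q * (p - 1), 1))
        order = np.argsort(-np.einsum("ij,ij->i", L, L))
        for u in order:
            if not np.any(L[u]):
                continue
            L_try = L.copy()
            L_try[u] = 0.0
            Psi_try = Psi.copy()
            Psi_try[u] += float(L[u] @ L[u])
            ll_try = _ll_gauss(S, L_try @ L_try.T + np.diag(Psi_try), n)
            if ll - ll_try < thresh:
                L, Psi, ll = L_try, Psi_try, ll_try
    return FactorModel(loadings=L, private_var=Psi, mean=mu, log_likelihood=float(ll),
                       ll_history=np.asarray(ll_hist), n_trials=n, converged=converged)


def shared_variance(model: FactorModel) -> np.ndarray:
    """Per-unit shared variance: diagonal of Lambda Lambda' (sign-invariant)."""
    return np.einsum("ij,ij->i", model.loadings, model.loadings)


def predict_leave_neuron_out(model: FactorModel, X) -> np.ndarray:
    """Predict each unit's counts from the other units' counts on each trial,
    using the model's Gaussian conditional expectation."""
    X = np.asarray(X, dtype=float)
    C = model.model_cov()
    p = model.n_units
    pred = np.empty_like(X)
    for u in range(p):
        others = np.delete(np.arange(p), u)
        Coo = C[np.ix_(others, others)]
        Cuo = C[u, others]
        w = np.linalg.solve(Coo, Cuo)
        pred[:, u] = model.mean[u] + (X[:, others] - model.mean[others]) @ w
    return pred


def cv_dimensionality(counts, q_list=(1, 2, 3, 4, 5), folds: int = 5,
                      seed: int | None = 0, sig_alpha: float = 0.05) -> CVReport:
    """Choose the latent dimensionality by fivefold leave-neuron-out CV.

    Per fold, a model of each candidate q is fitted on the training trials
    and every unit's held-out-trial counts are predicted from the other
    units; the per-q RMSE is averaged over folds.  The chosen q is the
    smallest one not significantly worse (paired t-test over folds) than the
    best q.
    """
    from scipy import stats as sps

    X = np.asarray(counts, dtype=float)
    n = X.shape[0]
    if folds > n:
        raise ValueError(f"folds ({folds}) exceed trials ({n})")
    if n < 2 * folds:
        raise ValueError("need at least 2 trials per fold")
    q_list = list(q_list)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    rmse = np.zeros((len(q_list), folds))
    for fi, test_idx in enumerate(fold_ids):
        train_idx = np.setdiff1d(order, test_idx)
        for qi, q in enumerate(q_list):
            model = fit_factor_model(X[train_idx], q=q, seed=seed)
            pred = predict_leave_neuron_out(model, X[test_idx])
            rmse[qi, fi] = float(np.sqrt(np.mean((pred - X[test_idx]) ** 2)))
    mean_rmse = rmse.mean(axis=1)
    best = int(np.argmin(mean_rmse))
    chosen = q_list[best]
    for qi in range(best):
        if np.allclose(rmse[qi], rmse[best]):
            chosen = q_list[qi]
            break
        _, pval = sps.ttest_rel(rmse[qi], rmse[best])
        if not (mean_rmse[qi] > mean_rmse[best] and pval < sig_alpha):
            chosen = q_list[qi]
            break
    return CVReport(q_list=q_list, rmse_mean=mean_rmse, rmse_by_fold=rmse,
                    chosen_q=int(chosen), folds=folds)


def shared_variance_size_tuning(
    session: TrialSpikeData,
    window_ms: tuple[float, float] = FA_WINDOW_MS,
    baseline_window_ms: tuple[float, float] = FA_BASELINE_WINDOW_MS,
    q: int = 1,
    seed: int | None = 0,
    fit_curves: bool = True,
    n_restarts: int = 20,
):
    """Per-unit shared-variance size tuning.

    A separate single-factor model is fitted for every (penetration, layer,
    diameter) cell on 300 ms stimulus-window counts (and once per cell on
    baseline-window counts); per-unit shared variances are collected across
    diameters and, optionally, fitted with a summed double ratio-of-Gaussians.

    Returns a dict with ``unit_ids``, ``layers``, ``diameters``,
    ``shared_var`` (units x diameters, NaN where the cell was skipped),
    ``baseline_shared_var``, ``private_var`` and per-unit ``fits``.
    """
    stim = count_in_window(session, *window_ms, label="fa_stim")
    base = count_in_window(session, *baseline_window_ms, label="fa_base")
    n_units = session.n_units
    n_diam = session.diameters.size
    sv = np.full((n_units, n_diam), np.nan)
    pv = np.full((n_units, n_diam), np.nan)
    sv_base = np.full(n_units, np.nan)

    pens = sorted({u.penetration for u in session.units})
    for pen in pens:
        for layer in LAYERS:
            idx = [i for i, u in enumerate(session.units)
                   if u.penetration == pen and u.layer == layer]
            if len(idx) < 2:
                logger.info("skipping penetration %s layer %s: %d unit(s) < 2",
                            pen, layer, len(idx))
                continue
            for di in range(n_diam):
                X = stim.counts[idx, di, :].T.astype(float)
                try:
                    model = fit_factor_model(X, q=q, seed=seed)
                except ValueError as e:
                    logger.info("FA skipped (pen %s, %s, diameter %d): %s",
                                pen, layer, di, e)
                    continue
                sv[idx, di] = shared_variance(model)
                pv[idx, di] = model.private_var
            Xb = base.counts[idx, :, :].transpose(1, 2, 0).reshape(-1, len(idx)).astype(float)
            try:
                bmodel = fit_factor_model(Xb, q=q, seed=seed)
                sv_base[idx] = shared_variance(bmodel)
            except ValueError as e:
                logger.info("baseline FA skipped (pen %s, %s): %s", pen, layer, e)

    fits: dict[str, DoubleRoGParams] = {}
    if fit_curves:
        for ui, u in enumerate(session.units):
            y = sv[ui]
            if np.any(~np.isfinite(y)) or n_diam < 6:
                continue
            fits[u.unit_id] = fit_double_rog(session.diameters, y, seed=seed,
                                             n_restarts=n_restarts)
    return {
        "unit_ids": [u.unit_id for u in session.units],
        "layers": [u.layer for u in session.units],
        "diameters": session.diameters.copy(),
        "shared_var": sv,
        "private_var": pv,
        "baseline_shared_var": sv_base,
        "fits": fits,
    }
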