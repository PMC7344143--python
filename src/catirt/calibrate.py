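"""Marginal maximum-likelihood calibration (Bock–Aitkin EM) for the GRM,
GPCM, and PCM, plus deviance/AIC/BIC model comparison.

The latent scale is identified by a fixed N(0,1) prior on a discrete
quadrature grid (61 equally spaced nodes on [-5, 5] by default); the prior
mean and variance are never re-estimated.  Threshold order is enforced by
the reparameterisation b_t = b_1 + cumsum(exp(delta_t)), which keeps every
returned item inside the ItemParameters invariant for all three models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .io import MISSING, ResponseMatrix
from .models import (
    DEFAULT_D,
    DEFAULT_GRID,
    PROB_FLOOR,
    ItemBank,
    ItemParameters,
    QuadratureGrid,
    category_probabilities,
)


class CalibrationError(ValueError):
    """Raised when a response matrix cannot support item calibration."""


@dataclass(frozen=True)
class ModelFitSummary:
    """Deviance and information-criterion summary of one calibrated model."""

    model: str
    deviance: float
    n_params: int
    n_persons: int
    converged: bool
    n_iter: int

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.deviance + self.n_params * np.log(self.n_persons)


def _n_categories(rm: ResponseMatrix) -> list[int]:
    ks = []
    for j, item_id in enumerate(rm.item_ids):
        col = rm.data[:, j]
        obs = col[col != MISSING]
        if obs.size == 0 or np.unique(obs).size < 2:
            raise CalibrationError(
                f"item {item_id}: fewer than 2 observed response categories"
            )
        if obs.min() < 0:
            raise CalibrationError(f"item {item_id}: negative response category")
        ks.append(int(obs.max()) + 1)
    return ks


def _pack(a: float, b: np.ndarray, model: str) -> np.ndarray:
    """Item parameters -> unconstrained optimiser vector."""
    b = np.asarray(b, dtype=float)
    gaps = np.maximum(np.diff(b), 1e-4)
    thr = np.concatenate([[b[0]], np.log(gaps)])
    if model == "PCM":
        return thr
    return np.concatenate([[np.log(a)], thr])


def _unpack(x: np.ndarray, model: str) -> tuple[float, np.ndarray]:
    if model == "PCM":
        a, thr = 1.0, x
    else:
        a, thr = float(np.exp(x[0])), x[1:]
    b = np.concatenate([[thr[0]], thr[0] + np.cumsum(np.exp(thr[1:]))])
    return a, b


def _category_table(a: float, b: np.ndarray, model: str, nodes: np.ndarray, D: float
                    ) -> np.ndarray:
    item = ItemParameters("_tmp", a, tuple(b), model)
    return category_probabilities(item, nodes, D=D)


def _initial_items(rm: ResponseMatrix, ks: list[int], model: str) -> list[tuple[float, np.ndarray]]:
    """Start values: unit slope, thresholds at normal quantiles of the
    observed cumulative category proportions."""
    inits = []
    for j, k in enumerate(ks):
        col = rm.data[:, j]
        obs = col[col != MISSING]
        b = []
        for t in range(1, k):
            p_ge = np.clip(np.mean(obs >= t), 0.02, 0.98)
            b.append(norm.ppf(1.0 - p_ge))
        b = np.asarray(b)
        for t in range(1, len(b)):  # enforce a strict start order
            b[t] = max(b[t], b[t - 1] + 1e-3)
        inits.append((1.0, b))
    return inits


def fit_model(
    responses: ResponseMatrix,
    model: str = "GRM",
    grid: QuadratureGrid = DEFAULT_GRID,
    max_iter: int = 200,
    tol: float = 1e-5,
    D: float = DEFAULT_D,
) -> tuple[ItemBank, ModelFitSummary]:
    """Calibrate item parameters by Bock–Aitkin EM.

    Returns the calibrated bank and a :class:`ModelFitSummary` whose
    deviance is -2 times the marginal log-likelihood at the solution.
    `tol` is the relative deviance change declaring convergence.
    """
    model = model.upper()
    if model not in ("GRM", "GPCM", "PCM"):
        raise ValueError(f"unknown model {model!r}")
    n = responses.n_persons
    if n == 0:
        raise CalibrationError("response matrix has no persons")
    if n < 50:
        warnings.warn(f"only {n} persons; calibration below n=50 is unstable")
    ks = _n_categories(responses)
    nodes, w = grid.nodes, grid.weights
    logw = np.log(w)
    params = _initial_items(responses, ks, model)
    data = responses.data
    obs_mask = data != MISSING

    def tables() -> list[np.ndarray]:
        return [_category_table(a, b, model, nodes, D) for a, b in params]

    def marginal_ll(tabs: list[np.ndarray]) -> tuple[float, np.ndarray]:
        loglik = np.zeros((n, nodes.size))
        for j, tab in enumerate(tabs):
            col = data[:, j]
            o = obs_mask[:, j]
            logtab = np.log(np.clip(tab, PROB_FLOOR, 1.0))
            loglik[o] += logtab[col[o]]
        joint = loglik + logw[None, :]
        ll_i = logsumexp(joint, axis=1)
        post = np.exp(joint - ll_i[:, None])
        return float(ll_i.sum()), post

    deviance = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tabs = tables()
        ll, post = marginal_ll(tabs)
        new_dev = -2.0 * ll
        if np.isfinite(deviance) and abs(deviance - new_dev) < tol * abs(deviance):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev

        # M-step: expected category counts r_{jtq}, then per-item Newton-type
        # maximisation of the expected complete-data log-likelihood.
        for j, k in enumerate(ks):
            col = data[:, j]
            o = obs_mask[:, j]
            r = np.zeros((k, nodes.size))
            np.add.at(r, col[o], post[o])

            def neg_q(x: np.ndarray) -> float:
                a, b = _unpack(x, model)
                tab = _category_table(a, b, model, nodes, D)
                return -float((r * np.log(np.clip(tab, PROB_FLOOR, 1.0))).sum())

            x0 = _pack(*params[j], model)
            res = optimize.minimize(neg_q, x0, method="L-BFGS-B")
            if res.fun <= neg_q(x0):  # generalised EM: never move downhill
                params[j] = _unpack(res.x, model)
    if not converged:
        warnings.warn(
            f"{model} calibration did not converge in {max_iter} EM iterations "
            f"(last deviance {deviance:.3f})"
        )
    else:
        # one final deviance at the accepted parameters
        deviance = -2.0 * marginal_ll(tables())[0]

    items = tuple(
        ItemParameters(item_id, a, tuple(b), model)
        for item_id, (a, b) in zip(responses.item_ids, params)
    )
    if model == "PCM":
        n_params = sum(k - 1 for k in ks)
    else:
        n_params = sum(k for k in ks)  # 1 slope + (k-1) thresholds each
    summary = ModelFitSummary(model, float(deviance), n_params, n, converged, it)
    return ItemBank(items, D=D), summary


def compare_models(
    responses: ResponseMatrix,
    models: tuple[str, ...] = ("GRM", "GPCM", "PCM"),
    grid: QuadratureGrid = DEFAULT_GRID,
    max_iter: int = 200,
    tol: float = 1e-5,
    D: float = DEFAULT_D,
) -> tuple[list[tuple[ItemBank, ModelFitSummary]], str]:
    """Fit each candidate model and rank by AIC (ties broken by BIC).

    Returns the fits sorted by AIC and the selected model tag.
    """
    if len(models) < 2:
        raise ValueError("model comparison needs at least 2 candidate models")
    fits = [
        fit_model(responses, m, grid=grid, max_iter=max_iter, tol=tol, D=D)
        for m in models
    ]
    fits.sort(key=lambda f: (f[1].aic, f[1].bic))
    return fits, fits[0][1].model


def eap_thetas(
    responses: ResponseMatrix,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised EAP trait estimates (posterior mean and SD) for every row.

    Missing responses are skipped.  Used by the QC stages; the CAT engine
    has its own incremental scorer that agrees with this one on shared
    grids.
    """
    nodes, w = grid.nodes, grid.weights
    n = responses.n_persons
    loglik = np.zeros((n, nodes.size))
    for item_id in responses.item_ids:
        if item_id not in bank.item_ids:
            continue
        j = responses.item_ids.index(item_id)
        tab = category_probabilities(bank.get(item_id), nodes, D=bank.D)
        col = responses.data[:, j]
        o = col != MISSING
        loglik[o] += np.log(np.clip(tab, PROB_FLOOR, 1.0))[col[o]]
    joint = loglik + np.log(w)[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    theta = post @ nodes
    var = (post * (nodes[None, :] - theta[:, None]) ** 2).sum(axis=1)
    return theta, np.sqrt(var)
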