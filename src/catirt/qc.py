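"""Item-bank quality control.

Six screening stages applied in a fixed order — unidimensionality (EFA
eigenvalue criteria), IRT model selection, local independence (Yen's Q3),
discrimination filtering, S-chi2 item fit, and logistic-regression DIF —
with the bank recalibrated after every stage that deletes items and an
audit trail recording each deletion and its reason.

Default thresholds: eigenvalue ratio > 4 with >= 20% first-factor
variance; Q3 > 0.36 (strict); discrimination >= 0.5; item-fit p < 0.01;
McFadden delta-R^2 > 0.02 (strict).  No multiple-testing correction is
applied; every statistic is recorded so users can post-correct.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import compare_models, eap_thetas, fit_model
from .io import MISSING, ResponseMatrix
from .models import DEFAULT_GRID, ItemBank, QuadratureGrid, category_probabilities


class QCError(ValueError):
    """Raised when a QC stage cannot run or empties the bank."""


# ---------------------------------------------------------------------------
# Unidimensionality


@dataclass
class UnidimReport:
    eigenvalues: np.ndarray
    ratio_1_2: float
    pct_var_first: float
    dropped_items: list[str]
    passed: bool
    n_iterations: int


def eigenvalue_ratio(eigenvalues: Sequence[float]) -> float:
    """First-to-second eigenvalue ratio of a factor solution."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        raise ValueError("need at least two eigenvalues")
    return float(ev[0] / ev[1])


def _pairwise_corr(rm: ResponseMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete Pearson correlations; constant items excluded."""
    df = rm.to_frame()
    constant = [c for c in df.columns if df[c].nunique(dropna=True) < 2]
    if constant:
        warnings.warn(f"constant items excluded from EFA: {constant}")
        df = df.drop(columns=constant)
    return df.corr(), constant


def _polychoric_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation of two ordinal variables.

    Thresholds come from the marginal category proportions; the latent
    correlation maximises the bivariate-normal contingency likelihood.
    """
    from scipy.optimize import minimize_scalar
    from scipy.stats import multivariate_normal, norm

    def cuts(v: np.ndarray) -> np.ndarray:
        cats = np.arange(v.min(), v.max() + 1)
        cum = np.cumsum([np.mean(v == c) for c in cats])[:-1]
        return norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6))

    cx = np.concatenate([[-np.inf], cuts(x), [np.inf]])
    cy = np.concatenate([[-np.inf], cuts(y), [np.inf]])
    counts, _, _ = np.histogram2d(
        x, y, bins=[np.arange(x.min() - 0.5, x.max() + 1), np.arange(y.min() - 0.5, y.max() + 1)]
    )

    def cell_prob(rho: float) -> np.ndarray:
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

        def rect(i, j):
            def F(a, b):
                if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                    return 0.0 if (np.isinf(a) and a < 0) or (np.isinf(b) and b < 0) else 1.0
                return mvn.cdf([min(a, 8), min(b, 8)])

            return (
                F(cx[i + 1], cy[j + 1]) - F(cx[i], cy[j + 1])
                - F(cx[i + 1], cy[j]) + F(cx[i], cy[j])
            )

        p = np.array(
            [[rect(i, j) for j in range(len(cy) - 1)] for i in range(len(cx) - 1)]
        )
        return np.clip(p, 1e-12, 1)

    def nll(rho: float) -> float:
        return -float((counts * np.log(cell_prob(rho))).sum())

    res = minimize_scalar(nll, bounds=(-0.995, 0.995), method="bounded")
    return float(res.x)


def _polychoric_corr(rm: ResponseMatrix) -> tuple[pd.DataFrame, list[str]]:
    df = rm.to_frame()
    constant = [c for c in df.columns if df[c].nunique(dropna=True) < 2]
    if constant:
        warnings.warn(f"constant items excluded from EFA: {constant}")
        df = df.drop(columns=constant)
    cols = list(df.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, j in itertools.combinations(range(len(cols)), 2):
        pair = df.iloc[:, [i, j]].dropna().to_numpy(dtype=int)
        rho = _polychoric_rho(pair[:, 0], pair[:, 1])
        mat.iloc[i, j] = mat.iloc[j, i] = rho
    return mat, constant


def _loadings(corr: np.ndarray, n_factors: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated principal-axis loadings and all eigenvalues."""
    ev, vec = np.linalg.eigh(corr)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    load = vec[:, :n_factors] * np.sqrt(np.maximum(ev[:n_factors], 0))
    # sign convention: first factor predominantly positive
    for f in range(load.shape[1]):
        if load[:, f].sum() < 0:
            load[:, f] = -load[:, f]
    return load, ev


def unidimensionality_check(
    responses: ResponseMatrix,
    loading_floor: float = 0.30,
    crossload_gap: float = 0.10,
    ratio_threshold: float = 4.0,
    pct_threshold: float = 20.0,
    polychoric: bool = False,
    max_iterations: int = 25,
) -> UnidimReport:
    """Iterative EFA screen for a dominant single factor.

    Items with a weak primary loading (< `loading_floor`) or comparable
    loadings on the first two unrotated factors (within `crossload_gap`)
    are dropped and the factor extraction re-run.  The surviving set passes
    when the first/second eigenvalue ratio exceeds `ratio_threshold` and
    the first factor explains at least `pct_threshold` percent of the total
    variance.
    """
    if responses.n_items < 3:
        raise QCError("unidimensionality check needs at least 3 items")
    corr_fn = _polychoric_corr if polychoric else _pairwise_corr
    corr, constant = corr_fn(responses)
    dropped = list(constant)
    current = list(corr.columns)
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        c = corr.loc[current, current].to_numpy()
        load, ev = _loadings(c)
        primary = np.abs(load[:, 0])
        cross = np.abs(np.abs(load[:, 0]) - np.abs(load[:, 1])) < crossload_gap
        bad = (primary < loading_floor) | cross
        if not bad.any() or len(current) - int(bad.sum()) < 3:
            break
        for idx in np.where(bad)[0]:
            dropped.append(current[idx])
        current = [c_ for k, c_ in enumerate(current) if not bad[k]]
    c = corr.loc[current, current].to_numpy()
    _, ev = _loadings(c)
    ratio = eigenvalue_ratio(ev)
    pct = 100.0 * float(ev[0]) / len(current)
    passed = ratio > ratio_threshold and pct >= pct_threshold
    return UnidimReport(ev, ratio, pct, dropped, passed, n_iter)


# ---------------------------------------------------------------------------
# Local independence (Yen's Q3)


@dataclass
class LocalDependenceReport:
    q3: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    dropped_items: list[str]
    max_abs_q3: float


def q3_screen(
    responses: ResponseMatrix,
    bank: ItemBank,
    thetas: np.ndarray,
    threshold: float = 0.36,
) -> LocalDependenceReport:
    """Yen's Q3 residual-correlation screen for local dependence.

    Q3 is the Pearson correlation, over persons, of the model residuals
    d_ij = x_ij - E[X_ij | theta_i].  Pairs with Q3 strictly above
    `threshold` are flagged; within each flagged pair the item with more
    flagged partners (ties broken by larger mean |Q3| over its flags, then
    by later bank position) is marked for deletion.
    """
    thetas = np.asarray(thetas, dtype=float)
    resid = np.full(responses.data.shape, np.nan)
    for j, item_id in enumerate(responses.item_ids):
        item = bank.get(item_id)
        probs = category_probabilities(item, thetas, D=bank.D)  # (K, n)
        expected = (np.arange(item.n_categories)[:, None] * probs).sum(axis=0)
        col = responses.data[:, j].astype(float)
        col[responses.data[:, j] == MISSING] = np.nan
        resid[:, j] = col - expected
    rdf = pd.DataFrame(resid, columns=responses.item_ids)
    degenerate = [c for c in rdf.columns if rdf[c].std(skipna=True) == 0]
    if degenerate:
        warnings.warn(f"zero-variance residuals; items skipped in Q3: {degenerate}")
        rdf = rdf.drop(columns=degenerate)
    q3 = rdf.corr()
    np.fill_diagonal(q3.values, np.nan)

    flagged: list[tuple[str, str, float]] = []
    ids = list(q3.columns)
    for i, j in itertools.combinations(range(len(ids)), 2):
        val = q3.iloc[i, j]
        if np.isfinite(val) and val > threshold:
            flagged.append((ids[i], ids[j], float(val)))

    flag_count: dict[str, int] = {}
    flag_vals: dict[str, list[float]] = {}
    for a, b, v in flagged:
        for x in (a, b):
            flag_count[x] = flag_count.get(x, 0) + 1
            flag_vals.setdefault(x, []).append(abs(v))
    dropped: set[str] = set()
    for a, b, _ in flagged:
        if a in dropped or b in dropped:
            continue
        key = lambda x: (flag_count[x], np.mean(flag_vals[x]), ids.index(x))
        dropped.add(max((a, b), key=key))
    max_abs = float(np.nanmax(np.abs(q3.to_numpy()))) if len(ids) > 1 else 0.0
    return LocalDependenceReport(
        q3, flagged, sorted(dropped, key=ids.index), max_abs
    )


# ---------------------------------------------------------------------------
# Discrimination filter


def discrimination_filter(
    bank: ItemBank, floor: float = 0.5
) -> tuple[list[str], list[str]]:
    """Split item ids into (kept, dropped) by the discrimination floor.

    The rule is strict: an item is dropped only when a < floor, so an item
    sitting exactly at the floor is retained.  Both lists are sorted by
    ascending discrimination.
    """
    by_a = sorted(bank, key=lambda it: it.a)
    kept = [it.item_id for it in by_a if not it.a < floor]
    dropped = [it.item_id for it in by_a if it.a < floor]
    return kept, dropped


# ---------------------------------------------------------------------------
# S-chi2 item fit (Orlando–Thissen)


@dataclass
class ItemFitResult:
    item_id: str
    s_chi2: float
    df: int
    p_value: float
    computable: bool = True


def _lord_wingersky(tables: list[np.ndarray]) -> np.ndarray:
    """Distribution of the summed score at each quadrature node.

    `tables` holds one (K_j, Q) category-probability array per item;
    returns (max_score + 1, Q).
    """
    dist = np.ones((1, tables[0].shape[1]))
    for tab in tables:
        k = tab.shape[0]
        new = np.zeros((dist.shape[0] + k - 1, dist.shape[1]))
        for c in range(k):
            new[c : c + dist.shape[0]] += dist * tab[c][None, :]
        dist = new
    return dist


def s_chi2_item_fit(
    responses: ResponseMatrix,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    min_expected: float = 1.0,
    alpha: float = 0.01,
) -> list[ItemFitResult]:
    """Orlando–Thissen S-chi2 fit statistic for every item.

    Observed category frequencies within rest-score groups (the summed
    score over the other items) are compared with the model-implied
    frequencies obtained from the Lord–Wingersky recursion over the
    quadrature prior.  Adjacent rest-score groups are collapsed until every
    expected cell reaches `min_expected`.  Rows with any missing response
    are excluded (the rest score is undefined for them).
    """
    complete = responses.mask.all(axis=1)
    if complete.sum() < responses.n_persons:
        warnings.warn(
            f"S-chi2 uses the {int(complete.sum())} fully observed rows only"
        )
    data = responses.data[complete]
    nodes, w = grid.nodes, grid.weights
    tables = {
        item_id: category_probabilities(bank.get(item_id), nodes, D=bank.D)
        for item_id in responses.item_ids
    }
    results: list[ItemFitResult] = []
    for j, item_id in enumerate(responses.item_ids):
        item = bank.get(item_id)
        k = item.n_categories
        others = [tables[i] for i in responses.item_ids if i != item_id]
        rest_dist = _lord_wingersky(others)  # (S+1, Q)
        n_scores = rest_dist.shape[0]
        # model-implied joint P(rest = s, X_j = c)
        joint = np.einsum("sq,cq,q->sc", rest_dist, tables[item_id], w)
        marg = joint.sum(axis=1)  # P(rest = s)

        rest = data.sum(axis=1) - data[:, j]
        observed = np.zeros((n_scores, k))
        np.add.at(observed, (rest, data[:, j]), 1.0)
        group_n = observed.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = joint / marg[:, None]  # P(X_j = c | rest = s)
        expected = group_n[:, None] * cond

        # collapse adjacent rest-score groups until all expected cells pass
        groups = [[s] for s in range(n_scores) if group_n[s] > 0]

        def cells(group: list[int]) -> tuple[np.ndarray, np.ndarray]:
            o = observed[group].sum(axis=0)
            e = expected[group]
            e = np.where(np.isfinite(e), e, 0.0).sum(axis=0)
            return o, e

        while len(groups) > 1:
            mins = [cells(g)[1].min() for g in groups]
            worst = int(np.argmin(mins))
            if mins[worst] >= min_expected:
                break
            neighbour = worst + 1 if worst == 0 else worst - 1
            if 0 < worst < len(groups) - 1:
                neighbour = worst - 1 if mins[worst - 1] < mins[worst + 1] else worst + 1
            lo, hi = sorted((worst, neighbour))
            groups[lo] = groups[lo] + groups[hi]
            del groups[hi]
        o_e = [cells(g) for g in groups]
        usable = [pair for pair in o_e if pair[1].min() >= min_expected]
        df = len(usable) * (k - 1) - (1 + (k - 1))
        if len(usable) < 2 or df < 1:
            results.append(ItemFitResult(item_id, np.nan, 0, np.nan, computable=False))
            continue
        chi2 = sum(float(((o - e) ** 2 / e).sum()) for o, e in usable)
        p = float(stats.chi2.sf(chi2, df))
        results.append(ItemFitResult(item_id, chi2, df, p))
    return results


# ---------------------------------------------------------------------------
# DIF by nested logistic regressions


@dataclass
class DIFResult:
    item_id: str
    r2_null: float
    r2_uniform: float
    r2_nonuniform: float
    flagged: bool
    computable: bool = True

    @property
    def delta_r2(self) -> float:
        return max(self.r2_nonuniform - self.r2_null, 0.0)


def _mcfadden_r2(y: np.ndarray, X: np.ndarray, ordinal: bool) -> float:
    """McFadden pseudo-R^2 of a binary or ordinal logistic regression.

    Falls back to a ridge-stabilised fit when the MLE fails to converge
    (e.g. under separation).
    """
    import statsmodels.api as sm
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ordinal:
            null = OrderedModel(y, np.empty((y.size, 0)), distr="logit").fit(
                method="bfgs", disp=False
            )
            try:
                full = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
                llf = full.llf
            except Exception:
                llf = np.nan
            if not np.isfinite(llf):
                full = OrderedModel(y, X, distr="logit").fit(
                    method="lbfgs", disp=False
                )
                llf = full.llf
            ll0 = null.llf
        else:
            Xc = sm.add_constant(X, has_constant="add")
            null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=False)
            try:
                full = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
                llf = full.llf
            except Exception:
                llf = np.nan
            if not np.isfinite(llf):
                warnings.warn("logistic separation; ridge-stabilised refit")
                full = sm.Logit(y, Xc).fit_regularized(
                    alpha=1e-4, L1_wt=0.0, disp=False
                )
                llf = full.llf
            ll0 = null.llf
    if ll0 == 0:
        return 0.0
    return float(1.0 - llf / ll0)


def dif_logistic(
    responses: ResponseMatrix,
    group: np.ndarray,
    matching: np.ndarray,
    threshold: float = 0.02,
    min_group_n: int = 30,
) -> list[DIFResult]:
    """Logistic-regression DIF screen with the McFadden delta-R^2 effect size.

    Three nested models are fitted per item — (1) matching trait only,
    (2) + group, (3) + group + group x matching — and the item is flagged
    when R^2(3) - R^2(1) strictly exceeds `threshold` (default 0.02).
    The matching variable is typically the EAP trait estimate.
    """
    group = np.asarray(group)
    matching = np.asarray(matching, dtype=float)
    levels = np.unique(group)
    if levels.size != 2:
        raise QCError(f"DIF needs exactly two groups, got levels {levels.tolist()}")
    g = (group == levels[1]).astype(float)
    for lv in levels:
        if (group == lv).sum() < min_group_n:
            warnings.warn(f"group {lv!r} has n < {min_group_n}; DIF may be unstable")
    results: list[DIFResult] = []
    for j, item_id in enumerate(responses.item_ids):
        col = responses.data[:, j]
        obs = col != MISSING
        y = col[obs]
        ordinal = np.unique(y).size > 2
        m, gg = matching[obs], g[obs]
        X1 = m[:, None]
        X2 = np.column_stack([m, gg])
        X3 = np.column_stack([m, gg, gg * m])
        try:
            r2 = [_mcfadden_r2(y, X, ordinal) for X in (X1, X2, X3)]
        except Exception as exc:  # pragma: no cover - degenerate data
            warnings.warn(f"DIF not computable for {item_id}: {exc}")
            results.append(
                DIFResult(item_id, np.nan, np.nan, np.nan, False, computable=False)
            )
            continue
        delta = max(r2[2] - r2[0], 0.0)
        results.append(
            DIFResult(item_id, r2[0], r2[1], r2[2], flagged=delta > threshold)
        )
    return results


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class QCConfig:
    """Thresholds and options for the staged QC pipeline (defaults are the
    conventional published cut-offs for each screen)."""

    loading_floor: float = 0.30
    crossload_gap: float = 0.10
    ratio_threshold: float = 4.0
    pct_threshold: float = 20.0
    polychoric: bool = False
    models: tuple[str, ...] = ("GRM",)
    q3_threshold: float = 0.36
    a_floor: float = 0.5
    fit_alpha: float = 0.01
    dif_threshold: float = 0.02
    max_iter: int = 200
    tol: float = 1e-5


@dataclass
class QCResult:
    bank: ItemBank
    model: str
    audit: list[dict]
    responses: ResponseMatrix  # surviving columns


def run_qc_pipeline(
    responses: ResponseMatrix,
    config: QCConfig | None = None,
    groups: np.ndarray | None = None,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> QCResult:
    """Run all QC stages in order and return the surviving calibrated bank.

    Stage order: unidimensionality -> model selection -> local independence
    -> discrimination -> item fit -> DIF (skipped when no group labels are
    supplied).  The bank is recalibrated after every stage that deletes
    items; the audit lists each stage's criterion and deletions.
    """
    cfg = config or QCConfig()
    audit: list[dict] = []

    def note(stage: str, criterion: str, dropped: list[str], **extra) -> None:
        audit.append({"stage": stage, "criterion": criterion, "dropped": list(dropped), **extra})

    uni = unidimensionality_check(
        responses,
        cfg.loading_floor,
        cfg.crossload_gap,
        cfg.ratio_threshold,
        cfg.pct_threshold,
        cfg.polychoric,
    )
    note(
        "unidimensionality",
        f"primary loading >= {cfg.loading_floor}, cross-loading gap >= {cfg.crossload_gap}; "
        f"pass if ratio > {cfg.ratio_threshold} and first-factor variance >= {cfg.pct_threshold}%",
        uni.dropped_items,
        ratio=uni.ratio_1_2,
        pct_var_first=uni.pct_var_first,
        passed=uni.passed,
    )
    keep = [i for i in responses.item_ids if i not in set(uni.dropped_items)]
    if not keep:
        raise QCError("unidimensionality screen removed every item")
    current = responses.subset_items(keep)

    def calibrate(rm: ResponseMatrix, model: str) -> ItemBank:
        bank, _ = fit_model(rm, model, grid=grid, max_iter=cfg.max_iter, tol=cfg.tol)
        return bank

    if len(cfg.models) >= 2:
        fits, model = compare_models(
            current, cfg.models, grid=grid, max_iter=cfg.max_iter, tol=cfg.tol
        )
        bank = next(b for b, s in fits if s.model == model)
        note(
            "model_selection",
            "argmin AIC (ties by BIC)",
            [],
            comparison=[
                {"model": s.model, "deviance": s.deviance, "aic": s.aic, "bic": s.bic}
                for _, s in fits
            ],
            selected=model,
        )
    else:
        model = cfg.models[0].upper()
        bank = calibrate(current, model)
        note("model_selection", "single candidate model", [], selected=model)

    thetas, _ = eap_thetas(current, bank, grid)
    ld = q3_screen(current, bank, thetas, cfg.q3_threshold)
    note(
        "local_independence",
        f"Q3 > {cfg.q3_threshold} (strict)",
        ld.dropped_items,
        flagged_pairs=[(a, b, v) for a, b, v in ld.flagged_pairs],
        max_abs_q3=ld.max_abs_q3,
    )
    if ld.dropped_items:
        keep = [i for i in current.item_ids if i not in set(ld.dropped_items)]
        current = current.subset_items(keep)
        bank = calibrate(current, model)

    kept, dropped_a = discrimination_filter(bank, cfg.a_floor)
    note("discrimination", f"a < {cfg.a_floor} dropped (strict)", dropped_a)
    if dropped_a:
        current = current.subset_items([i for i in current.item_ids if i in set(kept)])
        bank = calibrate(current, model)

    fit_results = s_chi2_item_fit(current, bank, grid)
    bad_fit = [
        r.item_id for r in fit_results if r.computable and r.p_value < cfg.fit_alpha
    ]
    note(
        "item_fit",
        f"S-chi2 p < {cfg.fit_alpha}",
        bad_fit,
        results=[
            {"item_id": r.item_id, "s_chi2": r.s_chi2, "df": r.df, "p": r.p_value}
            for r in fit_results
        ],
    )
    if bad_fit:
        current = current.subset_items(
            [i for i in current.item_ids if i not in set(bad_fit)]
        )
        if current.n_items == 0:
            raise QCError("item-fit screen removed every item")
        bank = calibrate(current, model)

    if groups is not None:
        thetas, _ = eap_thetas(current, bank, grid)
        dif_results = dif_logistic(current, groups, thetas, cfg.dif_threshold)
        dif_flagged = [r.item_id for r in dif_results if r.flagged]
        note(
            "dif",
            f"McFadden delta-R2 > {cfg.dif_threshold} (strict)",
            dif_flagged,
            results=[
                {"item_id": r.item_id, "delta_r2": r.delta_r2, "flagged": r.flagged}
                for r in dif_results
            ],
        )
        if dif_flagged:
            current = current.subset_items(
                [i for i in current.item_ids if i not in set(dif_flagged)]
            )
            if current.n_items == 0:
                raise QCError("DIF screen removed every item")
            bank = calibrate(current, model)
    else:
        note("dif", "skipped (no group labels supplied)", [])

    return QCResult(bank, model, audit, current)
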