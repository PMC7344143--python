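"""Item response models: 2PL / graded response model (GRM) and the
partial-credit family (GPCM/PCM) used for model comparison.

All response functions use the logistic metric with the scaling constant
D = 1.702, so that parameters are interpretable on the normal-ogive scale.
The 2PL is the two-category special case of the GRM and shares its code
path exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

#: Logistic scaling constant mapping the logistic metric onto the
#: normal-ogive metric.
DEFAULT_D = 1.702

#: Probability floor/ceiling applied inside logarithms so likelihoods of
#: extreme response patterns stay finite.
PROB_FLOOR = 1e-12

MODEL_TAGS = ("GRM", "GPCM", "PCM")


class CategoryIndexError(IndexError):
    """A category index fell outside an item's 1..K-1 threshold range."""


class ResponseDataError(ValueError):
    """A response category is inconsistent with the item it was scored on."""


@dataclass(frozen=True)
class ItemParameters:
    """Calibrated parameters of a single polytomous (or dichotomous) item.

    Parameters
    ----------
    item_id : str
        Unique identifier within a bank.
    a : float
        Discrimination (logistic slope); must be positive.
    b : tuple of float
        Ordered category thresholds, length K - 1 where K is the number of
        response categories.  A dichotomous item has a single threshold.
    model : str
        One of ``"GRM"``, ``"GPCM"``, ``"PCM"``.
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    model: str = "GRM"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "item_id", str(self.item_id))
        object.__setattr__(self, "a", float(self.a))
        if self.model not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model!r}")
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0, got {self.a}")
        if len(b) < 1:
            raise ValueError(f"item {self.item_id}: needs at least one threshold (K >= 2)")
        if any(b[i] > b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"item {self.item_id}: thresholds must be non-decreasing: {b}")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1

    @property
    def is_dichotomous(self) -> bool:
        return self.n_categories == 2


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of :class:`ItemParameters` with a shared scaling
    constant D (default 1.702)."""

    items: tuple[ItemParameters, ...]
    D: float = DEFAULT_D

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in bank: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> ItemParameters:
        return self.items[i]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index_of(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"item id {item_id!r} not in bank") from None

    def get(self, item_id: str) -> ItemParameters:
        return self.items[self.index_of(item_id)]

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        """New bank keeping only `item_ids`, preserving bank order."""
        keep = set(item_ids)
        missing = keep - set(self.item_ids)
        if missing:
            raise KeyError(f"item ids not in bank: {sorted(missing)}")
        return ItemBank(tuple(it for it in self.items if it.item_id in keep), D=self.D)


@dataclass(frozen=True)
class TraitEstimate:
    """A latent-trait point estimate with its standard error.

    The reliability attribute satisfies the identity rho = 1 - se**2,
    which ties the posterior standard deviation to the classical
    reliability of a test scored at that precision.
    """

    theta: float
    se: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValueError(f"standard error must be positive, got {self.se}")

    @property
    def reliability(self) -> float:
        return 1.0 - self.se**2


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature grid with prior weights normalised to sum to one."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D and conformable")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    @classmethod
    def standard_normal(cls, n_nodes: int = 401, bound: float = 5.0) -> "QuadratureGrid":
        """Equally spaced nodes on [-bound, bound] with N(0,1) prior weights.

        The two endpoint weights are halved (trapezoid rule), so grids of
        different resolution over the same interval integrate consistently.
        """
        nodes = np.linspace(-bound, bound, n_nodes)
        w = np.exp(-0.5 * nodes**2)
        w[0] *= 0.5
        w[-1] *= 0.5
        return cls(nodes, w)


DEFAULT_GRID = QuadratureGrid.standard_normal()


# ---------------------------------------------------------------------------
# Response functions


def cumulative_probability(
    item: ItemParameters, theta, t: int, D: float = DEFAULT_D
):
    """P(X >= t | theta) for the graded response model, t in 1..K-1.

    This is a 2PL curve in `theta` with slope ``D * a`` at threshold
    ``b[t-1]``; for a dichotomous item with t = 1 it is exactly the 2PL
    response function.
    """
    if not 1 <= t <= item.n_categories - 1:
        raise CategoryIndexError(
            f"category index t={t} out of range 1..{item.n_categories - 1} "
            f"for item {item.item_id}"
        )
    theta = np.asarray(theta, dtype=float)
    out = expit(D * item.a * (theta - item.b[t - 1]))
    return float(out) if out.ndim == 0 else out


def _grm_cumulatives(item: ItemParameters, theta: np.ndarray, D: float) -> np.ndarray:
    """Stack of P(X >= t) for t = 0..K, with boundary rows 1 and 0.

    Returns an array of shape (K + 1,) + theta.shape.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.b)[:, None]
    inner = expit(D * item.a * (theta[None, :] - b))
    ones = np.ones((1,) + theta.shape)
    zeros = np.zeros((1,) + theta.shape)
    return np.concatenate([ones, inner, zeros], axis=0)


def _pcm_family_probabilities(
    item: ItemParameters, theta: np.ndarray, D: float
) -> np.ndarray:
    """Category probabilities for GPCM/PCM (exponential-sum form).

    P(X = t) is proportional to exp(sum_{v<=t} D a (theta - b_v)); the PCM
    is the same form with the slope fixed at 1.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a = 1.0 if item.model == "PCM" else item.a
    b = np.asarray(item.b)
    steps = D * a * (theta[None, :] - b[:, None])  # (K-1, n)
    z = np.concatenate([np.zeros((1, theta.size)), np.cumsum(steps, axis=0)], axis=0)
    z -= z.max(axis=0, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=0, keepdims=True)


def category_probabilities(
    item: ItemParameters, theta, D: float = DEFAULT_D
) -> np.ndarray:
    """Vector of P(X = t | theta) for t = 0..K-1.

    GRM probabilities are adjacent differences of the cumulative curves,
    with the conventions P(X >= 0) = 1 and P(X >= K) = 0.  If `theta` is an
    array the result has shape (K,) + theta.shape.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if item.model in ("GPCM", "PCM"):
        probs = _pcm_family_probabilities(item, theta_arr, D)
    else:
        star = _grm_cumulatives(item, theta_arr, D)
        probs = star[:-1] - star[1:]
        np.clip(probs, 0.0, 1.0, out=probs)
    if np.ndim(theta) == 0:
        return probs[:, 0]
    return probs


def item_information(item: ItemParameters, theta, D: float = DEFAULT_D):
    """Fisher information of one item at `theta`.

    For the GRM this is the Samejima form
    ``I(theta) = sum_t (P*'_t - P*'_{t+1})^2 / P_t`` where ``P*_t`` is the
    cumulative curve and ``P*'`` its derivative ``D a P* (1 - P*)``.  For
    K = 2 it reduces to the 2PL information ``D^2 a^2 P (1 - P)``.  GPCM and
    PCM use ``D^2 a^2 Var(T | theta)``.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if item.model in ("GPCM", "PCM"):
        a = 1.0 if item.model == "PCM" else item.a
        probs = _pcm_family_probabilities(item, theta_arr, D)
        t = np.arange(item.n_categories, dtype=float)[:, None]
        mean = (t * probs).sum(axis=0)
        var = ((t - mean[None, :]) ** 2 * probs).sum(axis=0)
        info = (D * a) ** 2 * var
    else:
        star = _grm_cumulatives(item, theta_arr, D)
        dstar = D * item.a * star * (1.0 - star)  # boundaries give 0 exactly
        probs = np.clip(star[:-1] - star[1:], PROB_FLOOR, 1.0)
        info = ((dstar[:-1] - dstar[1:]) ** 2 / probs).sum(axis=0)
    if np.ndim(theta) == 0:
        return float(info[0])
    return info


def test_information(
    bank: ItemBank, theta, subset: Sequence[str] | None = None
):
    """Sum of item informations over `subset` (all items when None)."""
    items = bank.items if subset is None else [bank.get(i) for i in subset]
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros_like(theta_arr)
    for it in items:
        total = total + item_information(it, theta_arr, D=bank.D)
    if np.ndim(theta) == 0:
        return float(total[0])
    return total


def reliability_from_information(information: float) -> float:
    """Reliability implied by test information: rho = 1 - 1/I.

    Valid for a latent trait standardised to mean 0 and variance 1, where
    the squared standard error is the reciprocal of the information.
    """
    if information <= 0:
        raise ValueError(f"information must be positive, got {information}")
    return 1.0 - 1.0 / information


def se_from_information(information: float) -> float:
    """Standard error implied by test information: SE = 1 / sqrt(I)."""
    if information <= 0:
        raise ValueError(f"information must be positive, got {information}")
    return 1.0 / np.sqrt(information)


def se_from_reliability(rho: float) -> float:
    """Standard-error threshold equivalent to a reliability target."""
    if not rho < 1:
        raise ValueError(f"reliability target must be < 1, got {rho}")
    return float(np.sqrt(1.0 - rho))


def log_likelihood(
    responses, bank: ItemBank, thetas, missing: int = -1
) -> float:
    """Joint log-likelihood of a person x item response matrix.

    `responses` holds integer categories 0..K-1 with `missing` marking
    unobserved cells; missing cells contribute nothing.  `thetas` gives one
    latent-trait value per row.
    """
    resp = np.asarray(responses)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if resp.ndim != 2 or resp.shape[1] != len(bank):
        raise ResponseDataError(
            f"response matrix has {resp.shape} shape; expected n x {len(bank)}"
        )
    if resp.shape[0] != thetas.size:
        raise ResponseDataError("one theta per response row required")
    total = 0.0
    for j, item in enumerate(bank):
        col = resp[:, j]
        obs = col != missing
        if not obs.any():
            continue
        if col[obs].min() < 0 or col[obs].max() >= item.n_categories:
            bad = int(np.where(obs & ((col < 0) | (col >= item.n_categories)))[0][0])
            raise ResponseDataError(
                f"item {item.item_id}: response {col[bad]} in row {bad} outside "
                f"categories 0..{item.n_categories - 1}"
            )
        probs = category_probabilities(item, thetas[obs], D=bank.D)
        p = probs[col[obs], np.arange(obs.sum())]
        total += float(np.log(np.clip(p, PROB_FLOOR, 1.0)).sum())
    return total


def response_probability_matrix(
    bank: ItemBank, nodes: np.ndarray
) -> list[np.ndarray]:
    """Per-item category probability tables over quadrature nodes.

    Returns a list with one (K_j, n_nodes) array per item; the workhorse
    lookup for EAP scoring and EM calibration.
    """
    return [category_probabilities(it, np.asarray(nodes, float), D=bank.D) for it in bank]
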