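"""Synthetic respondents and the packaged narcissism item bank.

The generator draws graded-response-model data for theta ~ N(0,1) samples
and can plant three kinds of item defects — a weakly discriminating item,
a uniform threshold shift for one demographic group (DIF), and a shared
residual factor between two items (local dependence) — plus a binary
criterion label linked to theta through a logistic model.  Every draw is
reproducible from the design's seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import MISSING, ResponseMatrix, file_sha256
from .models import ItemBank, ItemParameters, category_probabilities

#: sha256 of the versioned bank fixture, recorded when the file was frozen.
BANK_SHA256 = "26fe859c586409d3350dc663e391f76c2ee223a8867eb1ffafc311d5c3462aba"


class BankIntegrityError(RuntimeError):
    """The packaged item-bank fixture does not match its recorded checksum."""


def _bank_path():
    return importlib.resources.files("catirt.data") / "narcissism_bank.csv"


def load_narcissism_bank_table() -> pd.DataFrame:
    """The packaged 85-item narcissism bank as a data frame.

    Includes the classical-test-theory difficulty/discrimination columns and
    the item-fit p-values alongside the IRT parameters.
    """
    path = _bank_path()
    if file_sha256(path) != BANK_SHA256:
        raise BankIntegrityError(
            "packaged bank fixture failed its checksum; the file was modified"
        )
    return pd.read_csv(path)


def load_narcissism_bank() -> ItemBank:
    """The calibrated 85-item narcissistic-personality bank.

    Items 1-68 are dichotomous (a single threshold); items 69-85 are
    five-category graded items with four ordered thresholds.
    """
    df = load_narcissism_bank_table()
    items = []
    for _, row in df.iterrows():
        b = tuple(float(row[c]) for c in ("b1", "b2", "b3", "b4") if pd.notna(row[c]))
        items.append(ItemParameters(str(row["item_id"]), float(row["a"]), b, "GRM"))
    return ItemBank(tuple(items))


# ---------------------------------------------------------------------------
# Defect plans


@dataclass(frozen=True)
class LowDiscrimination:
    item_id: str
    a: float = 0.3


@dataclass(frozen=True)
class DifShift:
    """Uniform DIF: shift all thresholds of `item_id` by `delta` for the
    focal group (group label 1), making the item harder for that group."""

    item_id: str
    delta: float = 0.6


@dataclass(frozen=True)
class LocalDependence:
    """Shared standard-normal residual added (scaled by `strength`) to the
    latent propensity of both partner items."""

    item_id: str
    partner_id: str
    strength: float = 1.0


Defect = LowDiscrimination | DifShift | LocalDependence


@dataclass
class SimulationDesign:
    """Conditions for one synthetic-respondent draw.

    `criterion_intercept`/`criterion_slope` define the logistic link
    P(label = 1 | theta) = expit(intercept + slope * theta); the defaults
    give a criterion of moderate prevalence that correlates with the trait
    the way an external diagnostic screen would.
    """

    bank: ItemBank
    n_persons: int
    seed: int
    thetas: np.ndarray | None = None
    defects: Sequence[Defect] = field(default_factory=tuple)
    group_fraction: float = 0.5
    criterion_intercept: float = -1.0
    criterion_slope: float = 1.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for a simulation design")
        ids = set(self.bank.item_ids)
        for d in self.defects:
            refs = [d.item_id] + ([d.partner_id] if isinstance(d, LocalDependence) else [])
            for r in refs:
                if r not in ids:
                    raise ValueError(f"defect references unknown item {r!r}")


@dataclass
class SimulatedData:
    responses: ResponseMatrix
    thetas: np.ndarray
    groups: np.ndarray
    criterion: np.ndarray
    bank: ItemBank  # the generating bank with defects applied


def _apply_bank_defects(bank: ItemBank, defects: Sequence[Defect]) -> ItemBank:
    items = {it.item_id: it for it in bank}
    for d in defects:
        if isinstance(d, LowDiscrimination):
            old = items[d.item_id]
            items[d.item_id] = ItemParameters(old.item_id, d.a, old.b, old.model)
    return ItemBank(tuple(items[i] for i in bank.item_ids), D=bank.D)


def draw_responses(
    item: ItemParameters, thetas: np.ndarray, rng: np.random.Generator, D: float
) -> np.ndarray:
    """Inverse-CDF draw of one item's categories at each person's theta."""
    probs = category_probabilities(item, thetas, D=D)  # (K, n)
    cum = np.cumsum(probs, axis=0)
    u = rng.random(thetas.size)
    return (u[None, :] > cum).sum(axis=0).astype(np.int64)


def simulate_responses(design: SimulationDesign) -> SimulatedData:
    """Draw a full synthetic data set under `design`.

    Responses come from the graded response model at each person's true
    theta, with DIF threshold shifts applied to the focal group and local
    dependence induced by a shared residual factor.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_persons
    thetas = (
        rng.standard_normal(n)
        if design.thetas is None
        else np.asarray(design.thetas, dtype=float)
    )
    if thetas.shape != (n,):
        raise ValueError("thetas must have length n_persons")
    groups = (rng.random(n) < design.group_fraction).astype(np.int64)

    gen_bank = _apply_bank_defects(design.bank, design.defects)
    dif = {d.item_id: d for d in design.defects if isinstance(d, DifShift)}
    shared: dict[str, tuple[np.ndarray, float]] = {}
    for d in design.defects:
        if isinstance(d, LocalDependence):
            z = rng.standard_normal(n)
            shared[d.item_id] = (z, d.strength)
            shared[d.partner_id] = (z, d.strength)

    data = np.empty((n, len(gen_bank)), dtype=np.int64)
    for j, item in enumerate(gen_bank):
        eff_theta = thetas.copy()
        if item.item_id in shared:
            z, strength = shared[item.item_id]
            eff_theta = eff_theta + strength * z
        if item.item_id in dif:
            delta = dif[item.item_id].delta
            shifted = ItemParameters(
                item.item_id, item.a, tuple(t + delta for t in item.b), item.model
            )
            focal = groups == 1
            data[~focal, j] = draw_responses(item, eff_theta[~focal], rng, gen_bank.D)
            data[focal, j] = draw_responses(shifted, eff_theta[focal], rng, gen_bank.D)
        else:
            data[:, j] = draw_responses(item, eff_theta, rng, gen_bank.D)

    p_crit = expit(design.criterion_intercept + design.criterion_slope * thetas)
    criterion = (rng.random(n) < p_crit).astype(np.int64)
    rm = ResponseMatrix(data, list(gen_bank.item_ids))
    return SimulatedData(rm, thetas, groups, criterion, gen_bank)


def generate_bank(
    n_items: int,
    n_categories: int | Sequence[int] = 2,
    seed: int = 0,
    a_range: tuple[float, float] = (0.7, 2.2),
    b_range: tuple[float, float] = (-2.0, 2.0),
) -> ItemBank:
    """A random GRM bank for simulation studies.

    Discriminations are uniform on `a_range`; thresholds are sorted uniform
    draws on `b_range` with a minimum gap of 0.3 between adjacent
    thresholds of a polytomous item.
    """
    rng = np.random.default_rng(seed)
    ks = [n_categories] * n_items if np.isscalar(n_categories) else list(n_categories)
    if len(ks) != n_items:
        raise ValueError("n_categories list must have length n_items")
    items = []
    for j, k in enumerate(ks):
        a = rng.uniform(*a_range)
        b = np.sort(rng.uniform(*b_range, size=k - 1))
        b = b + 0.3 * np.arange(k - 1)  # enforce spacing between thresholds
        b = b - b.mean() + rng.uniform(-0.5, 0.5)
        items.append(ItemParameters(f"i{j + 1}", a, tuple(b), "GRM"))
    return ItemBank(tuple(items))
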