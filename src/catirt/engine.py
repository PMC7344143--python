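"""Adaptive test administration.

The loop follows the classic five-block design: a calibrated bank, a
random starting item, maximum-Fisher-information (MFI) item selection at
the current trait estimate, EAP scoring after every response, and a
stopping rule that terminates once the estimate's reliability (1 - SE^2)
reaches its target or a hard item cap (default 35) is hit.

Two administration modes are supported.  *Recorded* mode replays a
complete response row collected conventionally, as if it had been gathered
adaptively (post-hoc simulation); *generative* mode draws each response
from the model at a known true theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .models import (
    DEFAULT_GRID,
    PROB_FLOOR,
    ItemBank,
    QuadratureGrid,
    TraitEstimate,
    category_probabilities,
    item_information,
    se_from_reliability,
    test_information,
)
from .simulate import draw_responses


@dataclass(frozen=True)
class StoppingRule:
    """Stop once reliability >= `rho_target`, or at `max_items`.

    `rho_target=None` disables the precision criterion so the test runs to
    the item cap (used for full-bank administration).  The reliability
    criterion is equivalent to SE <= sqrt(1 - rho_target).
    """

    rho_target: float | None = None
    max_items: int = 35

    def __post_init__(self) -> None:
        if self.rho_target is not None and not 0 < self.rho_target < 1:
            raise ValueError(f"rho_target must be in (0,1), got {self.rho_target}")
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")

    @property
    def se_threshold(self) -> float | None:
        return None if self.rho_target is None else se_from_reliability(self.rho_target)

    @property
    def label(self) -> str:
        return "none" if self.rho_target is None else f"rho>={self.rho_target:.2f}"


@dataclass
class CATRecord:
    """Per-person administration trace."""

    person_id: str
    administered: list[str]
    responses: list[int]
    theta_trace: list[float]
    se_trace: list[float]
    stop_reason: str  # reliability_met | max_items | bank_exhausted
    final: TraitEstimate

    def __post_init__(self) -> None:
        k = len(self.administered)
        if not (len(self.responses) == len(self.theta_trace) == len(self.se_trace) == k):
            raise ValueError("trace lengths must equal the number of administered items")
        if len(set(self.administered)) != k:
            raise ValueError("an item was administered twice")

    @property
    def n_items(self) -> int:
        return len(self.administered)


def start_item(bank: ItemBank, rng: np.random.Generator | int) -> str:
    """Uniformly random first item; reproducible given a seeded generator."""
    if len(bank) == 0:
        raise ValueError("cannot start a CAT on an empty bank")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return bank.item_ids[int(rng.integers(len(bank)))]


def select_next(
    bank: ItemBank, administered: Sequence[str], current: TraitEstimate
) -> str:
    """Maximum-Fisher-information selection at the current theta estimate.

    Ties are broken by bank order (lowest index), keeping selection
    deterministic.
    """
    used = set(administered)
    best_id, best_info = None, -np.inf
    for it in bank:
        if it.item_id in used:
            continue
        info = item_information(it, current.theta, D=bank.D)
        if info > best_info:
            best_id, best_info = it.item_id, info
    if best_id is None:
        raise LookupError("all items in the bank have been administered")
    return best_id


def eap_estimate(
    bank: ItemBank,
    item_ids: Sequence[str],
    responses: Sequence[int],
    grid: QuadratureGrid = DEFAULT_GRID,
) -> TraitEstimate:
    """Expected-a-posteriori trait estimate from the responses given so far.

    The posterior is the N(0,1)-weighted grid prior times the GRM
    likelihood; with no responses the prior itself is returned as
    TraitEstimate(0, 1).  Likelihood terms are accumulated in bank order so
    the estimate is bit-identical regardless of administration order.
    """
    if len(item_ids) != len(responses):
        raise ValueError("item_ids and responses must align")
    if len(item_ids) == 0:
        return TraitEstimate(0.0, 1.0)
    by_index = sorted(
        zip(item_ids, responses), key=lambda pair: bank.index_of(pair[0])
    )
    log_post = np.log(grid.weights)
    for item_id, resp in by_index:
        item = bank.get(item_id)
        if not 0 <= resp < item.n_categories:
            raise ValueError(
                f"response {resp} outside categories of item {item_id}"
            )
        probs = category_probabilities(item, grid.nodes, D=bank.D)[resp]
        log_post = log_post + np.log(np.clip(probs, PROB_FLOOR, 1.0))
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    theta = float(post @ grid.nodes)
    var = float(post @ (grid.nodes - theta) ** 2)
    return TraitEstimate(theta, float(np.sqrt(var)))


def _reliability(est: TraitEstimate, bank, administered, use_information: bool) -> float:
    if use_information:
        info = test_information(bank, est.theta, administered)
        return 1.0 - 1.0 / info if info > 0 else -np.inf
    return est.reliability


def run_cat(
    bank: ItemBank,
    rule: StoppingRule,
    seed: np.random.Generator | int,
    recorded: Mapping[str, int] | Sequence[int] | None = None,
    true_theta: float | None = None,
    person_id: str = "0",
    grid: QuadratureGrid = DEFAULT_GRID,
    use_information: bool = False,
    missing_policy: str = "skip",
) -> CATRecord:
    """Administer one adaptive test.

    Exactly one of `recorded` (a complete response row over the bank, given
    as a mapping or a bank-ordered sequence; None/-1 marks missing) or
    `true_theta` (generative mode) must be supplied.  The stop criterion is
    checked after each response is scored; the first item is always
    answered.  With `use_information=True` the reliability check uses
    1 - 1/I at the current theta instead of the EAP posterior SD.
    """
    if (recorded is None) == (true_theta is None):
        raise ValueError("supply exactly one of `recorded` or `true_theta`")
    if missing_policy not in ("skip", "abort"):
        raise ValueError("missing_policy must be 'skip' or 'abort'")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer, list)) else seed
    row: dict[str, int] = {}
    if recorded is not None:
        if not isinstance(recorded, Mapping):
            if len(recorded) != len(bank):
                raise ValueError("recorded row must cover the whole bank")
            recorded = dict(zip(bank.item_ids, recorded))
        row = {k: v for k, v in recorded.items()}

    administered: list[str] = []
    responses: list[int] = []
    theta_trace: list[float] = []
    se_trace: list[float] = []
    excluded: set[str] = set()  # skipped due to missing recorded responses
    est = TraitEstimate(0.0, 1.0)
    next_id = start_item(bank, rng)
    stop_reason = None
    while True:
        if recorded is not None:
            resp = row.get(next_id)
            resp = None if resp is None or resp == -1 else int(resp)
            if resp is None:
                if missing_policy == "abort":
                    raise ValueError(
                        f"person {person_id}: missing recorded response for "
                        f"selected item {next_id}"
                    )
                warnings.warn(
                    f"person {person_id}: no recorded response for {next_id}; skipped"
                )
                excluded.add(next_id)
                remaining = set(bank.item_ids) - set(administered) - excluded
                if not remaining:
                    stop_reason = "bank_exhausted"
                    break
                next_id = select_next(bank, administered + list(excluded), est)
                continue
        else:
            item = bank.get(next_id)
            resp = int(draw_responses(item, np.array([true_theta]), rng, bank.D)[0])

        administered.append(next_id)
        responses.append(resp)
        est = eap_estimate(bank, administered, responses, grid)
        theta_trace.append(est.theta)
        se_trace.append(est.se)

        if (
            rule.rho_target is not None
            and _reliability(est, bank, administered, use_information) >= rule.rho_target
        ):
            stop_reason = "reliability_met"
            break
        if len(administered) >= rule.max_items:
            stop_reason = "max_items"
            break
        remaining = set(bank.item_ids) - set(administered) - excluded
        if not remaining:
            stop_reason = "bank_exhausted"
            break
        next_id = select_next(bank, administered + list(excluded), est)

    return CATRecord(
        person_id, administered, responses, theta_trace, se_trace, stop_reason, est
    )


def batch_simulate(
    bank: ItemBank,
    rules: Sequence[StoppingRule],
    seed: int,
    thetas: Sequence[float] | None = None,
    recorded: np.ndarray | None = None,
    grid: QuadratureGrid = DEFAULT_GRID,
    use_information: bool = False,
) -> dict[str, list[CATRecord]]:
    """Run a CAT for every person under every stopping rule.

    In generative mode (`thetas` given) a complete response matrix is drawn
    once from the bank and then replayed in recorded mode under each rule —
    the post-hoc design, which also makes rules comparable on identical
    responses.  Per-person randomness (the starting item) derives from the
    master seed and the person index, so the same person starts on the same
    item under every rule.
    """
    if (thetas is None) == (recorded is None):
        raise ValueError("supply exactly one of `thetas` or `recorded`")
    if thetas is not None:
        thetas = np.asarray(thetas, dtype=float)
        rows = np.empty((thetas.size, len(bank)), dtype=np.int64)
        rng = np.random.default_rng([seed, 0])
        for j, item in enumerate(bank):
            rows[:, j] = draw_responses(item, thetas, rng, bank.D)
    else:
        rows = np.asarray(recorded)
        if rows.shape[1] != len(bank):
            raise ValueError("recorded matrix must have one column per bank item")
    out: dict[str, list[CATRecord]] = {}
    for rule in rules:
        records = []
        for i in range(rows.shape[0]):
            records.append(
                run_cat(
                    bank,
                    rule,
                    seed=[seed, 1, i],
                    recorded=rows[i],
                    person_id=str(i),
                    grid=grid,
                    use_information=use_information,
                )
            )
        out[rule.label] = records
    return out


def full_bank_estimates(
    bank: ItemBank,
    rows: np.ndarray,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """EAP theta and SE for every row under full (non-adaptive)
    administration of the bank; the paper-and-pencil reference scores."""
    from .calibrate import eap_thetas
    from .io import ResponseMatrix

    rm = ResponseMatrix(np.asarray(rows), list(bank.item_ids))
    return eap_thetas(rm, bank, grid)
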