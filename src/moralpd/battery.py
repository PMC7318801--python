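"""Dilemma battery representation and constrained presentation orders.

A battery for one experimental condition holds 10 *pairs* of moral dilemmas:
each pair couples an incongruent scenario (the harmful action maximizes
overall benefit, so harm-rejection and outcome-maximization conflict) with a
congruent twin (the benefit of acting is minimized, so both inclinations
favor rejection).  Both members of a pair share the condition's
instrumentality (harm as means vs. side-effect) and personal-force
(personal vs. impersonal) levels.

Presentation orders are semi-random: a valid order is a permutation of the
20 items in which (a) no more than three congruent or three incongruent
items occur consecutively and (b) at least six other dilemmas separate the
two members of every pair.  Orders are drawn by rejection sampling of
uniform permutations, which is uniform over the set of valid orders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"

#: Constraint defaults: maximum same-congruency run length, and minimum
#: number of other items strictly between the two members of a pair.
MAX_RUN = 3
MIN_BETWEEN = 6


@dataclass(frozen=True)
class DilemmaItem:
    """One scenario of a congruent/incongruent dilemma pair."""

    item_id: str
    pair_id: str
    congruency: str
    instrumentality: str
    personal_force: str
    counterbalance_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.congruency not in (CONGRUENT, INCONGRUENT):
            raise ValueError(f"unknown congruency {self.congruency!r}")


@dataclass(frozen=True)
class PresentationOrder:
    """A seed-stamped permutation of one condition's 20 item ids."""

    item_ids: tuple
    seed: int
    condition: tuple  # (instrumentality, personal_force)


def standard_battery(instrumentality: str, personal_force: str) -> list[DilemmaItem]:
    """A well-formed 20-item battery (10 pairs) for one condition.

    Item ids encode the condition and pair, e.g. ``me-pe-P03-inc`` for the
    incongruent member of pair 3 in the means/personal cell.
    """
    prefix = f"{instrumentality[:2]}-{personal_force[:2]}"
    items = []
    for k in range(1, 11):
        pair = f"{prefix}-P{k:02d}"
        for cong, tag in ((INCONGRUENT, "inc"), (CONGRUENT, "con")):
            items.append(
                DilemmaItem(
                    item_id=f"{pair}-{tag}",
                    pair_id=pair,
                    congruency=cong,
                    instrumentality=instrumentality,
                    personal_force=personal_force,
                )
            )
    return items


def validate_battery(items: Iterable[DilemmaItem]) -> list[str]:
    """Check battery well-formedness; violations are returned, not raised.

    A well-formed battery has exactly 10 pairs, each with one congruent and
    one incongruent member, uniform instrumentality and personal force
    within a pair, and unique item ids.
    """
    items = list(items)
    if not items:
        raise ValueError("empty battery")
    violations: list[str] = []

    seen_ids: set[str] = set()
    for it in items:
        if it.item_id in seen_ids:
            violations.append(f"duplicate item_id {it.item_id!r}")
        seen_ids.add(it.item_id)

    by_pair: dict[str, list[DilemmaItem]] = {}
    for it in items:
        by_pair.setdefault(it.pair_id, []).append(it)

    for pair_id, members in sorted(by_pair.items()):
        congs = sorted(m.congruency for m in members)
        if len(members) != 2 or congs != [CONGRUENT, INCONGRUENT]:
            violations.append(
                f"unpaired or malformed pair {pair_id!r}: congruencies {congs}"
            )
        if len({(m.instrumentality, m.personal_force) for m in members}) > 1:
            violations.append(f"factor mismatch within pair {pair_id!r}")

    if len(by_pair) != 10:
        violations.append(f"expected 10 pairs, found {len(by_pair)}")
    if len(items) != 20:
        violations.append(f"expected 20 items, found {len(items)}")
    return violations


def _require_well_formed(items: Sequence[DilemmaItem]) -> None:
    violations = validate_battery(items)
    if violations:
        raise ValueError("battery is not well-formed: " + "; ".join(violations))


def validate_order(
    order: Sequence[str] | PresentationOrder,
    items: Sequence[DilemmaItem],
    max_run: int = MAX_RUN,
    min_between: int = MIN_BETWEEN,
) -> list[str]:
    """Check a presentation order against both sequencing constraints.

    Returns a list of violation strings: runs of more than ``max_run``
    same-congruency items, and pairs whose members have fewer than
    ``min_between`` other items strictly between them.  A non-permutation
    input raises ``ValueError``.
    """
    ids = list(order.item_ids) if isinstance(order, PresentationOrder) else list(order)
    by_id = {it.item_id: it for it in items}
    if sorted(ids) != sorted(by_id):
        raise ValueError("order is not a permutation of the battery's item ids")

    violations: list[str] = []

    run_len, run_cong = 0, None
    for pos, item_id in enumerate(ids):
        cong = by_id[item_id].congruency
        if cong == run_cong:
            run_len += 1
        else:
            run_len, run_cong = 1, cong
        if run_len == max_run + 1:  # report each offending run once
            violations.append(
                f"run of >{max_run} {cong} items ending at position {pos}"
            )

    pos_of = {item_id: pos for pos, item_id in enumerate(ids)}
    pairs: dict[str, list[int]] = {}
    for item_id, pos in pos_of.items():
        pairs.setdefault(by_id[item_id].pair_id, []).append(pos)
    for pair_id, positions in sorted(pairs.items()):
        a, b = sorted(positions)
        between = b - a - 1
        if between < min_between:
            violations.append(
                f"pair {pair_id!r} members at positions {a} and {b} "
                f"({between} items between, need >= {min_between})"
            )
    return violations


def _order_items(items: Sequence[DilemmaItem]) -> list[DilemmaItem]:
    """Canonical item layout: incongruent members of pairs 1..10, then their
    congruent twins in the same pair order (positions k and k+10 are a pair)."""
    inc = sorted(
        (it for it in items if it.congruency == INCONGRUENT), key=lambda it: it.pair_id
    )
    by_pair = {it.pair_id: it for it in items if it.congruency == CONGRUENT}
    return inc + [by_pair[it.pair_id] for it in inc]


def _valid_position_perms(
    rng: np.random.Generator,
    n_perms: int,
    max_run: int,
    min_between: int,
) -> np.ndarray:
    """Vectorized rejection step: draw ``n_perms`` uniform permutations and
    return those satisfying both constraints, as position-of-item arrays.

    ``pos[i, k]`` is the position of canonical item ``k`` (pairs are the
    columns ``k`` and ``k + 10``).  The rare pair-distance constraint is
    checked first, directly on positions; only survivors pay for the inverse
    permutation needed by the run-length check.
    """
    # argsort of iid random keys is a uniform permutation; interpreted as
    # position-of-item (its inverse, also uniform, would be item-at-position).
    # 32-bit integer keys sort measurably faster than doubles; the collision
    # probability per row is ~4e-8 and a collision still yields a permutation.
    keys = rng.integers(0, 2**32, size=(n_perms, 20), dtype=np.uint32)
    pos = np.argsort(keys, axis=1)
    gap = np.abs(pos[:, :10] - pos[:, 10:])
    pos = pos[(gap >= min_between + 1).all(axis=1)]
    if not len(pos):
        return pos

    item_at = np.argsort(pos, axis=1)
    cong_at = item_at >= 10  # canonical items 10..19 are congruent
    ok = np.ones(len(pos), dtype=bool)
    run = np.ones(len(pos), dtype=np.int64)
    for j in range(1, 20):
        run = np.where(cong_at[:, j] == cong_at[:, j - 1], run + 1, 1)
        ok &= run <= max_run
    return pos[ok]


def generate_orders(
    items: Sequence[DilemmaItem],
    n_orders: int,
    seed: int,
    max_attempts: int = 400_000_000,
    max_run: int = MAX_RUN,
    min_between: int = MIN_BETWEEN,
    batch: int = 400_000,
) -> list[PresentationOrder]:
    """Draw ``n_orders`` valid presentation orders by rejection sampling.

    Deterministic given ``seed``.  Raises ``RuntimeError`` if the battery is
    so constrained that ``max_attempts`` uniform permutations do not yield
    enough valid orders (with the default constraints the acceptance rate is
    about 1e-4, so the default budget is ample).
    """
    items = list(items)
    _require_well_formed(items)
    canon = _order_items(items)
    condition = (canon[0].instrumentality, canon[0].personal_force)
    rng = np.random.default_rng(seed)

    collected: list[np.ndarray] = []
    n_found = 0
    attempts = 0
    while n_found < n_orders:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"over-constrained battery: {n_found}/{n_orders} valid orders "
                f"after {attempts} attempts"
            )
        n_draw = min(batch, max_attempts - attempts)
        good = _valid_position_perms(rng, n_draw, max_run, min_between)
        attempts += n_draw
        if len(good):
            collected.append(good)
            n_found += len(good)

    pos = np.concatenate(collected)[:n_orders]
    item_at = np.argsort(pos, axis=1)
    orders = []
    for row in item_at:
        orders.append(
            PresentationOrder(
                item_ids=tuple(canon[k].item_id for k in row),
                seed=seed,
                condition=condition,
            )
        )
    return orders


def generate_order(
    items: Sequence[DilemmaItem],
    seed: int,
    max_attempts: int = 5_000_000,
    max_run: int = MAX_RUN,
    min_between: int = MIN_BETWEEN,
) -> PresentationOrder:
    """Draw one valid presentation order (see :func:`generate_orders`)."""
    return generate_orders(
        items, 1, seed, max_attempts=max_attempts, max_run=max_run,
        min_between=min_between, batch=20_000,
    )[0]


def freeze_orders(
    items: Sequence[DilemmaItem], seed: int, n_orders: int = 5
) -> list[PresentationOrder]:
    """The study design fixed five semi-random orders per condition."""
    return generate_orders(items, n_orders, seed)


# ---------------------------------------------------------------- file I/O

def battery_to_frame(items: Iterable[DilemmaItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": it.item_id,
            "pair_id": it.pair_id,
            "congruency": it.congruency,
            "instrumentality": it.instrumentality,
            "personal_force": it.personal_force,
            "counterbalance_tags": ";".join(sorted(it.counterbalance_tags)),
        }
        for it in items
    )


def battery_from_frame(df: pd.DataFrame) -> list[DilemmaItem]:
    items = []
    for rec in df.to_dict("records"):
        tags = rec.get("counterbalance_tags") or ""
        if isinstance(tags, float):  # NaN from an empty CSV cell
            tags = ""
        items.append(
            DilemmaItem(
                item_id=str(rec["item_id"]),
                pair_id=str(rec["pair_id"]),
                congruency=str(rec["congruency"]),
                instrumentality=str(rec["instrumentality"]),
                personal_force=str(rec["personal_force"]),
                counterbalance_tags=frozenset(t for t in str(tags).split(";") if t),
            )
        )
    return items


def save_battery(items: Iterable[DilemmaItem], path: str | Path) -> None:
    battery_to_frame(items).to_csv(path, index=False)


def load_battery(path: str | Path) -> list[DilemmaItem]:
    return battery_from_frame(pd.read_csv(path))


def save_orders(orders: Iterable[PresentationOrder], path: str | Path) -> None:
    payload = [
        {
            "item_ids": list(o.item_ids),
            "seed": o.seed,
            "condition": list(o.condition),
        }
        for o in orders
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_orders(path: str | Path) -> list[PresentationOrder]:
    payload = json.loads(Path(path).read_text())
    return [
        PresentationOrder(
            item_ids=tuple(o["item_ids"]),
            seed=int(o["seed"]),
            condition=tuple(o["condition"]),
        )
        for o in payload
    ]
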