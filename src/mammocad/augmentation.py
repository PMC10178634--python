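"""Class-balancing geometric augmentation and stratified splitting.

Unbalanced image classes are brought to an exact per-class target using
only three geometric operations — horizontal flip, vertical flip, and 90°
(counter-clockwise) rotation — applied in deterministic rounds of
operation chains. Chains that reproduce an earlier transform (the three
generators span only 7 distinct non-identity transforms of the square) are
skipped within a cycle; once exhausted, the chain list cycles again so any
target multiplier is reachable. The enumeration is truncated to exactly
``target - initial`` items with a seeded shuffle of the final round, and
every source image is used before any is reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OPERATIONS",
    "ClassInventory",
    "PlanItem",
    "AugmentationPlan",
    "apply_chain",
    "distinct_chains",
    "plan_augmentation",
    "execute_plan",
    "dataset_totals",
    "split_train_test",
]

# rot90 is counter-clockwise (numpy convention).
OPERATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "flip_h": np.fliplr,
    "flip_v": np.flipud,
    "rot90": np.rot90,
}

#: Lexicographic operation order used for chain enumeration.
OP_ORDER = ("flip_h", "flip_v", "rot90")


@dataclass
class ClassInventory:
    """Bookkeeping for one image class: how many there are, how many wanted."""

    name: str
    initial_count: int
    target: int
    refs: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.initial_count < 0 or self.target < 0:
            raise ValueError("counts must be non-negative")
        if self.refs is None:
            self.refs = list(range(self.initial_count))
        if len(self.refs) != self.initial_count:
            raise ValueError(
                f"{len(self.refs)} refs but initial_count={self.initial_count}"
            )


@dataclass(frozen=True)
class PlanItem:
    """One image to generate: a source reference and an operation chain."""

    source: object
    chain: tuple[str, ...]


@dataclass
class AugmentationPlan:
    class_name: str
    items: list[PlanItem]
    seed: int

    def __len__(self) -> int:
        return len(self.items)


def apply_chain(image: np.ndarray, chain: Sequence[str]) -> np.ndarray:
    """Apply a sequence of named operations left to right."""
    out = np.asarray(image)
    for op in chain:
        try:
            out = OPERATIONS[op](out)
        except KeyError:
            raise ValueError(f"unknown operation {op!r}") from None
    return out


def _transform_key(chain: Sequence[str]) -> bytes:
    # Identify a chain by its action on an asymmetric 3x3 marker; this
    # captures the dihedral-group element the chain composes to.
    marker = np.arange(9, dtype=np.int64).reshape(3, 3)
    return apply_chain(marker, chain).tobytes()


def distinct_chains(max_rounds: int = 8) -> list[list[tuple[str, ...]]]:
    """Enumerate operation chains grouped by round (= chain length).

    Round r lists all length-r chains in lexicographic operation order
    whose composed transform is new (not the identity and not equal, as a
    transform, to any earlier chain). Enumeration stops at the first empty
    round; the three generators yield 7 distinct transforms in 3 rounds.
    """
    identity = _transform_key(())
    seen = {identity}
    rounds: list[list[tuple[str, ...]]] = []
    prev: list[tuple[str, ...]] = [()]
    for _ in range(max_rounds):
        this_round: list[tuple[str, ...]] = []
        nxt: list[tuple[str, ...]] = []
        for base in prev:
            for op in OP_ORDER:
                chain = base + (op,)
                nxt.append(chain)
                key = _transform_key(chain)
                if key not in seen:
                    seen.add(key)
                    this_round.append(chain)
        if not this_round:
            break
        rounds.append(this_round)
        prev = nxt
    return rounds


def plan_augmentation(inventory: ClassInventory, seed: int = 0) -> AugmentationPlan:
    """Plan exactly ``target - initial`` generated images for one class.

    Rounds of chains are laid out deterministically (each chain applied to
    every source in order); full rounds are taken whole and the final
    partial round is truncated with a seeded shuffle. When all distinct
    transforms are exhausted the chain rounds cycle again, so targets
    larger than ``8 * initial`` are reachable (with repeated content, as
    any purely geometric scheme must).
    """
    if inventory.initial_count < 1:
        raise ValueError(f"class {inventory.name!r} has no images to augment")
    if inventory.target < inventory.initial_count:
        raise ValueError(
            f"target {inventory.target} below initial count {inventory.initial_count}"
        )
    needed = inventory.target - inventory.initial_count
    items: list[PlanItem] = []
    rounds = distinct_chains()
    rng = np.random.default_rng(seed)
    while needed > 0:
        for chains in rounds:
            block = [
                PlanItem(source=ref, chain=chain)
                for chain in chains
                for ref in inventory.refs
            ]
            if needed >= len(block):
                items.extend(block)
                needed -= len(block)
            elif needed > 0:
                order = rng.permutation(len(block))[:needed]
                items.extend(block[i] for i in sorted(order))
                needed = 0
            if needed == 0:
                break
    return AugmentationPlan(class_name=inventory.name, items=items, seed=seed)


def execute_plan(
    plan: AugmentationPlan, images: dict
) -> list[tuple[object, tuple[str, ...], np.ndarray]]:
    """Generate the planned images.

    ``images`` maps source references to arrays. Returns a list of
    ``(source_ref, chain, image)`` triples in plan order.
    """
    out = []
    for item in plan.items:
        if item.source not in images:
            raise KeyError(f"missing source image {item.source!r}")
        out.append((item.source, item.chain, apply_chain(images[item.source], item.chain)))
    return out


def dataset_totals(inventories: Sequence[ClassInventory]) -> int:
    """Total image count of a dataset after all classes reach target."""
    return int(sum(inv.target for inv in inventories))


def split_train_test(
    refs: Sequence, ratio: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Seeded train/test split of one class's references.

    Training receives ``floor(ratio * n)`` items; test the remainder, so
    the two parts always sum to the class size.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    refs = list(refs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(refs))
    n_train = int(np.floor(ratio * len(refs)))
    train = [refs[i] for i in sorted(order[:n_train])]
    test = [refs[i] for i in sorted(order[n_train:])]
    return train, test
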