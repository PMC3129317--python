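"""Synthetic trees and Mk-evolved characters with recorded ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`simulate_yule_tree` — a pure-birth (Yule) tree: while i lineages
  exist the next speciation waits Exp(lambda * i); a uniformly chosen lineage
  splits.  The result is ultrametric with expected root-to-tip depth
  sum_{i=2..n} 1/(lambda i).

* :func:`simulate_mk_character` — event-level (Gillespie) simulation of an
  Mk1 character down the tree: along each branch the state leaves at total
  rate (k-1) r, jumping to one of the other states uniformly.  Every jump is
  recorded, so the true node states and the true per-branch change history
  are available as ground truth — not just the endpoints.

:func:`make_study_like_dataset` emulates the scale of the scallop study: an
81-tip tree, a 6-state character rooted in the byssal-attaching state, with
the rate calibrated so the expected number of changes on the tree is ~17.
Simulated states use codes 1..k, so code 0 stays reserved for missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CharacterMatrix, Phylogeny
from .transitions import TransitionMatrix, TransitionRecord, build_transition_matrix

#: calibration target: expected number of character changes on the tree,
#: matching the study's 17 observed life-habit transitions
DEFAULT_TARGET_CHANGES = 17.0


@dataclass(frozen=True)
class Change:
    """One simulated state jump on the branch subtending ``child_id``."""

    child_id: str
    from_state: int
    to_state: int
    time: float  # offset from the parent end of the branch


@dataclass
class SimulatedHistory:
    """Ground truth from the Mk simulator.

    ``true_changes`` composes exactly to ``true_node_states`` along every
    branch (asserted at construction).
    """

    tree: Phylogeny
    true_node_states: dict[str, int]
    true_changes: list[Change]
    rate: float
    seed: int | None = None
    k: int = 0

    def __post_init__(self) -> None:
        by_branch: dict[str, list[Change]] = {}
        for ch in self.true_changes:
            by_branch.setdefault(ch.child_id, []).append(ch)
        for v in self.tree.preorder:
            if v == self.tree.root:
                continue
            child = self.tree.labels[v]
            state = self.true_node_states[self.tree.labels[self.tree.parent[v]]]
            for ch in sorted(by_branch.get(child, []), key=lambda c: c.time):
                if ch.from_state != state:
                    raise ValueError(
                        f"change history inconsistent on branch to {child}"
                    )
                state = ch.to_state
            if state != self.true_node_states[child]:
                raise ValueError(f"endpoint state mismatch on branch to {child}")

    @property
    def n_changes(self) -> int:
        return len(self.true_changes)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator | None = None
) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` tips; deterministic given a seed."""
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    children: list[list[int]] = [[1, 2], [], []]
    lengths: list[float] = [0.0, 0.0, 0.0]
    active: list[int] = [1, 2]
    while True:
        i = len(active)
        t = rng.exponential(1.0 / (birth_rate * i))
        for v in active:
            lengths[v] += t
        if i == n_tips:
            break
        j = int(rng.integers(i))
        v = active.pop(j)
        for _ in range(2):
            c = len(children)
            children.append([])
            lengths.append(0.0)
            children[v].append(c)
            active.append(c)
    labels: list[str | None] = [None] * len(children)
    for rank, v in enumerate(sorted(active), start=1):
        labels[v] = f"t{rank}"
    return Phylogeny(children, lengths, labels)


def simulate_mk_character(
    tree: Phylogeny,
    k: int,
    rate: float,
    root_state: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulatedHistory:
    """Gillespie simulation of an Mk1 character along every branch.

    States are coded 1..k.  ``root_state=None`` draws the root from the
    stationary (uniform) distribution.  Every intermediate jump is recorded
    with its position on the branch.
    """
    if k < 2 or k > 6:
        raise ValueError("k must be between 2 and 6 (codes 1..6; 0 is missing)")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = list(range(1, k + 1))
    if root_state is None:
        root_state = int(rng.choice(states))
    elif root_state not in states:
        raise ValueError(f"root_state {root_state} outside 1..{k}")

    node_states: dict[str, int] = {tree.labels[tree.root]: root_state}
    changes: list[Change] = []
    leave_rate = (k - 1) * rate
    for v in tree.preorder:
        if v == tree.root:
            continue
        s = node_states[tree.labels[tree.parent[v]]]
        t = float(tree.lengths[v])
        tau = 0.0
        if leave_rate > 0:
            while True:
                tau += rng.exponential(1.0 / leave_rate)
                if tau > t:
                    break
                new = int(rng.choice([x for x in states if x != s]))
                changes.append(Change(tree.labels[v], s, new, tau))
                s = new
        node_states[tree.labels[v]] = s
    seed_int = seed if isinstance(seed, int) else None
    return SimulatedHistory(
        tree=tree, true_node_states=node_states, true_changes=changes,
        rate=rate, seed=seed_int, k=k,
    )


def character_matrix_from_history(history: SimulatedHistory) -> CharacterMatrix:
    """Tip states of a simulated history as a CharacterMatrix."""
    tree = history.tree
    return CharacterMatrix(
        {tree.labels[v]: history.true_node_states[tree.labels[v]]
         for v in tree.tip_indices}
    )


def true_transition_records(history: SimulatedHistory) -> list[TransitionRecord]:
    """Net (endpoint) state changes per branch of a simulated history.

    This is the quantity an endpoint-based transition enumeration estimates;
    branches with multiple hits that return to the parent state contribute no
    record here even though ``true_changes`` logs the events.
    """
    tree = history.tree
    records: list[TransitionRecord] = []
    for v in tree.preorder:
        if v == tree.root:
            continue
        parent = tree.labels[tree.parent[v]]
        child = tree.labels[v]
        a = history.true_node_states[parent]
        b = history.true_node_states[child]
        if a != b:
            records.append(TransitionRecord(parent, child, a, b))
    return records


def true_transition_matrix(history: SimulatedHistory) -> TransitionMatrix:
    """Endpoint-change count matrix of a simulated history (codes 1..k)."""
    return build_transition_matrix(
        true_transition_records(history),
        state_space=list(range(1, history.k + 1)),
    )


def make_study_like_dataset(
    seed: int | None,
    n_tips: int = 81,
    k: int = 6,
    root_state: int = 2,
    target_changes: float = DEFAULT_TARGET_CHANGES,
    birth_rate: float = 1.0,
) -> tuple[Phylogeny, CharacterMatrix, SimulatedHistory]:
    """Tree + character emulating the study's conditions, with ground truth.

    81 tips, six states, a byssal-attaching (code 2) root, and a rate
    calibrated on the realised tree so the expected number of character
    changes is ``target_changes``: the Gillespie event count is Poisson with
    mean (k-1) * r * L for total tree length L, so r = target / ((k-1) L)
    exactly (no search needed).
    """
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_tips, birth_rate=birth_rate, seed=rng)
    rate = target_changes / ((k - 1) * tree.total_length)
    history = simulate_mk_character(tree, k=k, rate=rate, root_state=root_state, seed=rng)
    if isinstance(seed, int):
        history.seed = seed
    matrix = character_matrix_from_history(history)
    return tree, matrix, history
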