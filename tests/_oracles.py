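"""Independent brute-force oracles used by the test suite.

These enumerate state assignments exhaustively and must stay independent of
the pruning / dynamic-programming code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from habitevol.io import MISSING_CODE, CharacterMatrix, Phylogeny
from habitevol.mk import MkModel, mk_transition_matrix


def _free_and_fixed(tree: Phylogeny, matrix: CharacterMatrix, space: list[int]):
    idx = {c: i for i, c in enumerate(space)}
    free, fixed = [], {}
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            code = matrix.entries[tree.labels[v]]
            if code == MISSING_CODE:
                free.append(v)
            else:
                fixed[v] = idx[code]
        else:
            free.append(v)
    return free, fixed


def exhaustive_log_likelihood(
    tree: Phylogeny, matrix: CharacterMatrix, model: MkModel,
    state_space: list[int] | None = None,
) -> float:
    """ln P(data) by summing over every full labeling of the tree."""
    space = state_space or matrix.state_space or list(range(1, model.k + 1))
    k = model.k
    lengths = tree.clamped_lengths()
    P = {
        v: mk_transition_matrix(model, lengths[v])
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    free, fixed = _free_and_fixed(tree, matrix, space)
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        p = 1.0 / k
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][assign[tree.parent[v]], assign[v]]
        total += p
    return math.log(total)


def exhaustive_marginals(
    tree: Phylogeny, matrix: CharacterMatrix, model: MkModel
) -> dict[str, np.ndarray]:
    """Per-node marginal probabilities by restricted exhaustive sums."""
    space = matrix.state_space
    k = model.k
    lengths = tree.clamped_lengths()
    P = {
        v: mk_transition_matrix(model, lengths[v])
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    free, fixed = _free_and_fixed(tree, matrix, space)
    joint = np.zeros((tree.n_nodes, k))
    for combo in itertools.product(range(k), repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        p = 1.0 / k
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][assign[tree.parent[v]], assign[v]]
        for v in range(tree.n_nodes):
            joint[v, assign[v]] += p
    return {
        tree.labels[v]: joint[v] / joint[v].sum() for v in range(tree.n_nodes)
    }


def exhaustive_parsimony(
    tree: Phylogeny, matrix: CharacterMatrix
) -> tuple[int, dict[str, frozenset[int]]]:
    """Minimum change count and MPR sets by enumerating all labelings."""
    space = matrix.state_space
    k = len(space)
    free, fixed = _free_and_fixed(tree, matrix, space)
    best = None
    achieving: dict[int, set[int]] = {v: set() for v in range(tree.n_nodes)}
    results = []
    for combo in itertools.product(range(k), repeat=len(free)):
        assign = dict(zip(free, combo))
        assign.update(fixed)
        changes = sum(
            1
            for v in range(tree.n_nodes)
            if v != tree.root and assign[v] != assign[tree.parent[v]]
        )
        results.append((changes, assign))
        if best is None or changes < best:
            best = changes
    for changes, assign in results:
        if changes == best:
            for v, s in assign.items():
                achieving[v].add(s)
    sets = {
        tree.labels[v]: frozenset(space[i] for i in achieving[v])
        for v in range(tree.n_nodes)
    }
    return best, sets


def pearson_chi_square(counts: list[int]) -> tuple[float, int]:
    """Textbook Pearson X^2 against a uniform expectation (no scipy)."""
    total = sum(counts)
    m = len(counts)
    exp = total / m
    stat = sum((o - exp) ** 2 / exp for o in counts)
    return stat, m - 1
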