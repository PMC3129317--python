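"""Unordered-parsimony ancestral states (generalized Fitch via unit-cost Sankoff).

Changes between states are unordered and cost 1 each.  The dynamic program is
run over the full subset lattice in two passes — a postorder (down) pass for
subtree costs and a preorder (up) pass for the cost of the rest of the tree —
so polytomies are handled natively and the reported per-node state sets are
exact MPR sets: the states a node takes in at least one most-parsimonious
reconstruction, not a single ACCTRAN/DELTRAN resolution.  Missing tips
(code 0) contribute zero cost for every state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING_CODE, CharacterMatrix, Phylogeny
from .mk import AsrResult


@dataclass
class ParsimonyResult:
    """Minimum change count and exact MPR state sets per node."""

    score: int
    node_state_sets: dict[str, frozenset[int]]
    state_space: list[int]


def fitch_score(tree: Phylogeny, matrix: CharacterMatrix) -> ParsimonyResult:
    """Minimum number of unordered state changes, with per-node MPR sets.

    Score 0 iff all non-missing tips share one state.  Raises if no tip
    carries a scored (non-missing) state.
    """
    space = list(matrix.state_space)
    if not space:
        raise ValueError("no scored tips: every taxon is missing (code 0)")
    k = len(space)
    idx = {c: i for i, c in enumerate(space)}
    n = tree.n_nodes
    BIG = n + 1  # exceeds any attainable change count

    down = np.zeros((n, k), dtype=int)
    for v in tree.tip_indices:
        code = matrix.entries[tree.labels[v]]
        if code != MISSING_CODE:
            down[v, :] = BIG
            down[v, idx[code]] = 0
    for v in tree.postorder:
        if tree.is_tip(v):
            continue
        for c in tree.children[v]:
            mc = down[c].min()
            down[v] += np.minimum(down[c], mc + 1)
    score = int(down[tree.root].min())

    # up pass: rest[v][s] = min changes outside subtree(v), incl. v's branch
    rest = np.zeros((n, k), dtype=int)
    for v in tree.preorder:
        for c in tree.children[v]:
            mc = down[c].min()
            excl = down[v] - np.minimum(down[c], mc + 1)
            base = rest[v] + excl
            b = base.min()
            rest[c] = np.minimum(base, b + 1)

    sets: dict[str, frozenset[int]] = {}
    for v in range(n):
        tot = down[v] + rest[v]
        sets[tree.labels[v]] = frozenset(
            space[i] for i in range(k) if tot[i] == score
        )
    return ParsimonyResult(score=score, node_state_sets=sets, state_space=space)


def compare_reconstructions(ml: AsrResult, mp: ParsimonyResult) -> pd.DataFrame:
    """Per-node agreement between ML best-state sets and parsimony MPR sets.

    A node agrees when the two sets intersect.  The returned frame carries the
    overall agreement fraction in ``df.attrs["agreement_fraction"]``.
    """
    if set(ml.best_state_set) != set(mp.node_state_sets):
        raise ValueError("reconstructions are from different trees (node sets differ)")
    rows = []
    for label in ml.best_state_set:
        mlset = ml.best_state_set[label]
        mpset = mp.node_state_sets[label]
        rows.append(
            {
                "node_id": label,
                "ml_best_set": ";".join(map(str, sorted(mlset))),
                "mp_state_set": ";".join(map(str, sorted(mpset))),
                "agree": bool(mlset & mpset),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["agreement_fraction"] = float(df["agree"].mean()) if len(df) else 1.0
    return df
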