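"""Single-rate Markov k-state (Mk1) likelihood and marginal ancestral states.

The Mk1 model is a continuous-time Markov chain on k unordered states with
one shared instantaneous rate r for every state-to-state change: Q has r on
every off-diagonal and -(k-1)r on the diagonal.  Its transition probabilities
have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k r t)
    P_ij(t) = 1/k - 1/k   * exp(-k r t)    (i != j)

Tree likelihoods are computed by postorder pruning with per-node rescaling;
per-node marginal state likelihoods by the standard two-pass (inside/outside)
algorithm, equivalent to rerooting at each node.  A node's state is called
"resolved" when every alternative state's log marginal likelihood falls more
than a threshold (default 2.0 log units) below the best state's; otherwise
the node is ambiguous and retains all states within the threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import MISSING_CODE, CharacterMatrix, Phylogeny, state_label

logger = logging.getLogger(__name__)

RATE_LOWER_BOUND = 1e-8


@dataclass
class MkModel:
    """Mk1 model: k states, one rate per unit branch length."""

    k: int
    rate: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("Mk model needs k >= 2 states")
        if not (self.rate >= 0):
            raise ValueError("rate must be >= 0")

    def q_matrix(self) -> np.ndarray:
        Q = np.full((self.k, self.k), self.rate)
        np.fill_diagonal(Q, -(self.k - 1) * self.rate)
        return Q


def mk_transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """P(t) for the Mk1 chain; rows sum to 1. Raises on negative t."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    k = model.k
    e = math.exp(-k * model.rate * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def _resolve_state_space(matrix: CharacterMatrix, model: MkModel) -> list[int]:
    """State space used for likelihood: observed codes, or 1..k if all missing."""
    space = list(matrix.state_space)
    if not space:
        return list(range(1, model.k + 1))
    if len(space) != model.k:
        raise ValueError(
            f"model has k={model.k} but matrix has {len(space)} observed states"
        )
    return space


def _tip_partials(
    tree: Phylogeny, matrix: CharacterMatrix, state_space: list[int]
) -> np.ndarray:
    k = len(state_space)
    idx = {c: i for i, c in enumerate(state_space)}
    D = np.zeros((tree.n_nodes, k))
    for v in tree.tip_indices:
        code = matrix.entries[tree.labels[v]]
        if code == MISSING_CODE:
            D[v, :] = 1.0  # missing data: all-ones partial
        else:
            D[v, idx[code]] = 1.0
    return D


def _branch_matrices(tree: Phylogeny, model: MkModel, lengths: np.ndarray) -> list:
    P = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if v != tree.root:
            P[v] = mk_transition_matrix(model, lengths[v])
    return P


def _down_pass(tree, D, P):
    """Postorder conditional likelihoods with per-node rescaling.

    Returns (D, logscale) where the true partial at node v is
    D[v] * exp(logscale[v]).
    """
    D = D.copy()
    logscale = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        if tree.is_tip(v):
            continue
        acc = np.ones(D.shape[1])
        sc = 0.0
        for c in tree.children[v]:
            acc = acc * (P[c] @ D[c])
            sc += logscale[c]
        m = acc.max()
        if not (m > 0) or not np.isfinite(m):
            raise ArithmeticError(
                f"non-finite/zero partial likelihood at node {tree.labels[v]}"
            )
        D[v] = acc / m
        logscale[v] = sc + math.log(m)
    return D, logscale


def tree_log_likelihood(
    tree: Phylogeny,
    matrix: CharacterMatrix,
    model: MkModel,
    min_branch_length: float | None = None,
) -> float:
    """ln P(tip states | tree, Mk1 model), uniform 1/k root prior.

    Missing tips (code 0) contribute an all-ones partial.  Branch lengths of
    zero are clamped (see :meth:`Phylogeny.clamped_lengths`).
    """
    space = _resolve_state_space(matrix, model)
    lengths = tree.clamped_lengths() if min_branch_length is None else tree.clamped_lengths(min_branch_length)
    D0 = _tip_partials(tree, matrix, space)
    P = _branch_matrices(tree, model, lengths)
    D, logscale = _down_pass(tree, D0, P)
    total = float(D[tree.root] @ np.full(model.k, 1.0 / model.k))
    lnl = math.log(total) + logscale[tree.root]
    if not np.isfinite(lnl):
        raise ArithmeticError(f"non-finite log-likelihood at root {tree.labels[tree.root]}")
    return lnl


def estimate_rate(
    tree: Phylogeny, matrix: CharacterMatrix, min_branch_length: float | None = None
) -> MkModel:
    """Maximum-likelihood rate for the Mk1 model, by bounded 1-D optimisation.

    The search interval is [1e-8, 1e3 / tree height].  An invariant character
    (all non-missing tips in one state) has its maximum at the lower bound; a
    warning is emitted and the bound returned.
    """
    observed = {c for c in matrix.entries.values() if c != MISSING_CODE}
    if len(observed) < 2:
        warnings.warn("invariant character: rate estimate at lower bound")
        return MkModel(k=max(matrix.k, 2), rate=RATE_LOWER_BOUND)
    model_k = matrix.k
    height = tree.height
    upper = 1e3 / height if height > 0 else 1e3

    def neg_lnl(r: float) -> float:
        return -tree_log_likelihood(
            tree, matrix, MkModel(model_k, r), min_branch_length
        )

    # the profile flattens onto its saturation asymptote at large r, which can
    # strand a single golden-section search there; bracket the optimum with a
    # log-spaced scan first, then refine locally
    grid = np.geomspace(RATE_LOWER_BOUND, upper, 41)
    vals = [neg_lnl(r) for r in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_lnl, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    best_r, best_f = float(res.x), float(res.fun)
    if vals[i] < best_f:
        best_r, best_f = float(grid[i]), float(vals[i])
    model = MkModel(model_k, best_r)
    logger.info("ML rate estimate r=%.6g (lnL=%.4f)", model.rate, -best_f)
    return model


@dataclass
class AsrResult:
    """Marginal ancestral state reconstruction under an Mk1 model.

    marginals
        node label -> posterior probability vector over ``state_space``.
    log_marginals
        node label -> natural log of each state's marginal likelihood
        (the quantity the delta-lnL decision rule compares).
    best_state_set
        node label -> set of state codes surviving the decision rule; a
        singleton marks the node resolved.
    """

    model: MkModel
    state_space: list[int]
    log_likelihood: float
    marginals: dict[str, np.ndarray]
    log_marginals: dict[str, np.ndarray]
    best_state_set: dict[str, frozenset[int]] = field(default_factory=dict)
    threshold: float = 2.0

    def resolved(self, label: str) -> bool:
        return len(self.best_state_set[label]) == 1


def apply_decision_rule(
    asr: AsrResult, threshold: float = 2.0
) -> dict[str, frozenset[int]]:
    """Per node, keep every state within ``threshold`` log units of the best.

    A difference strictly greater than the threshold rejects a state; a
    difference exactly equal to it leaves the state in play (the node stays
    ambiguous).  A singleton set marks the node resolved.
    """
    out: dict[str, frozenset[int]] = {}
    for label, lm in asr.log_marginals.items():
        best = lm.max()
        keep = frozenset(
            code for code, v in zip(asr.state_space, lm) if best - v <= threshold
        )
        out[label] = keep
    asr.best_state_set = out
    asr.threshold = threshold
    return out


def marginal_reconstruction(
    tree: Phylogeny,
    matrix: CharacterMatrix,
    model: MkModel | None = None,
    threshold: float = 2.0,
    min_branch_length: float | None = None,
) -> AsrResult:
    """Two-pass marginal ancestral state reconstruction.

    For every node the marginal likelihood of each state is the product of the
    "inside" partial (subtree below the node) and the "outside" partial
    (rest of the tree plus the uniform root prior); normalising gives the
    per-node posterior probabilities.  The decision rule is applied with the
    given threshold to produce best-state sets.
    """
    if model is None:
        model = estimate_rate(tree, matrix, min_branch_length)
    space = _resolve_state_space(matrix, model)
    k = model.k
    lengths = (
        tree.clamped_lengths()
        if min_branch_length is None
        else tree.clamped_lengths(min_branch_length)
    )
    D0 = _tip_partials(tree, matrix, space)
    P = _branch_matrices(tree, model, lengths)
    D, logD = _down_pass(tree, D0, P)

    # messages child -> parent: M[c] = P_c @ D[c], scaled by exp(logD[c])
    M = {}
    for v in range(tree.n_nodes):
        if v != tree.root:
            M[v] = P[v] @ D[v]

    U = np.zeros_like(D)
    logU = np.zeros(tree.n_nodes)
    U[tree.root] = np.full(k, 1.0 / k)  # root prior lives in the outside pass
    total = float(D[tree.root] @ U[tree.root])
    lnl = math.log(total) + logD[tree.root]

    for v in tree.preorder:
        ch = tree.children[v]
        if not ch:
            continue
        # prefix/suffix products of sibling messages (avoids division by 0)
        m = len(ch)
        pre = [np.ones(k)]
        for c in ch:
            pre.append(pre[-1] * M[c])
        suf = [np.ones(k) for _ in range(m + 1)]
        for i in range(m - 1, -1, -1):
            suf[i] = suf[i + 1] * M[ch[i]]
        for i, c in enumerate(ch):
            sib = pre[i] * suf[i + 1]
            vec = (U[v] * sib) @ P[c]
            s = vec.max()
            if not (s > 0) or not np.isfinite(s):
                raise ArithmeticError(
                    f"non-finite outside likelihood at node {tree.labels[c]}"
                )
            U[c] = vec / s
            sibscale = sum(logD[cc] for cc in ch if cc != c)
            logU[c] = logU[v] + sibscale + math.log(s)

    marginals: dict[str, np.ndarray] = {}
    log_marginals: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        joint = D[v] * U[v]
        tot = joint.sum()
        if not (tot > 0) or not np.isfinite(tot):
            raise ArithmeticError(f"degenerate marginals at node {tree.labels[v]}")
        node_lnl = math.log(tot) + logD[v] + logU[v]
        if abs(node_lnl - lnl) > 1e-6 * max(1.0, abs(lnl)):
            raise ArithmeticError(
                f"inconsistent marginal normalisation at node {tree.labels[v]}: "
                f"{node_lnl} vs {lnl}"
            )
        with np.errstate(divide="ignore"):
            lm = np.log(joint)
        lm = lm + logD[v] + logU[v]
        marginals[tree.labels[v]] = joint / tot
        log_marginals[tree.labels[v]] = lm

    asr = AsrResult(
        model=model,
        state_space=space,
        log_likelihood=lnl,
        marginals=marginals,
        log_marginals=log_marginals,
    )
    apply_decision_rule(asr, threshold)
    return asr


def asr_to_frame(asr: AsrResult, tree: Phylogeny) -> pd.DataFrame:
    """Tabular view of an :class:`AsrResult` (one row per node)."""
    rows = []
    for v in range(tree.n_nodes):
        lab = tree.labels[v]
        parent = tree.labels[tree.parent[v]] if v != tree.root else ""
        row: dict[str, object] = {"node_id": lab, "parent_id": parent}
        for code, p in zip(asr.state_space, asr.marginals[lab]):
            row[f"p_{state_label(code)}"] = p
        best = sorted(asr.best_state_set[lab])
        row["best_state_set"] = ";".join(str(c) for c in best)
        row["resolved"] = len(best) == 1
        rows.append(row)
    return pd.DataFrame(rows)


def write_asr_tsv(asr: AsrResult, tree: Phylogeny, path: str | Path) -> None:
    asr_to_frame(asr, tree).to_csv(path, sep="\t", index=False, float_format="%.6g")
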