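"""Resolve per-node states and enumerate ancestor -> descendant transitions.

Ancestral-state reconstruction yields a state *set* per node (singleton when
resolved).  To count transitions, sets are first collapsed to single states
under an ambiguity policy:

``inherit_parent``
    an ambiguous node takes its parent's assigned state when that state is in
    its own set (adding no change on the connecting branch); otherwise it
    stays unassigned.  This realises a minimal transition count among
    parent-propagating completions.
``skip_branch``
    ambiguous nodes stay unassigned; branches touching them contribute no
    transition.

A transition is then recorded for every branch whose two endpoints are
assigned different states (terminal branches included — single-species
origins count).  Row/column aggregation of the resulting matrix gives, for
each state, the number of transitions it sourced and the number of
independent origins (derivations) of it.

The printed study transition table (17 transitions among the six scallop
life-habit classes) is bundled as a fixture; see :func:`load_table2_records`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .io import Phylogeny, state_label


@dataclass(frozen=True)
class TransitionRecord:
    """One state change on one branch (parent -> child)."""

    parent_id: str
    child_id: str
    from_state: int
    to_state: int
    resolved: bool = True  # both endpoint state sets were singletons

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise ValueError("a transition must change state")


@dataclass
class TransitionMatrix:
    """Counts of from-state -> to-state changes; diagonal structurally zero."""

    counts: pd.DataFrame  # index = from_state codes, columns = to_state codes

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def state_space(self) -> list[int]:
        return list(self.counts.index)

    def labeled(self) -> pd.DataFrame:
        """Counts with human-readable state names on both axes."""
        df = self.counts.copy()
        df.index = [state_label(c) for c in df.index]
        df.columns = [state_label(c) for c in df.columns]
        df.index.name = "from"
        df.columns.name = "to"
        return df


def assign_states(
    state_sets: dict[str, frozenset[int]],
    tree: Phylogeny,
    policy: str = "inherit_parent",
) -> dict[str, int | None]:
    """Collapse per-node state sets to single states under an ambiguity policy.

    Resolved (singleton) nodes take their state.  See module docstring for the
    two policies; unresolvable nodes map to None.
    """
    if policy not in ("inherit_parent", "skip_branch"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    assigned: dict[str, int | None] = {}
    for v in tree.preorder:
        label = tree.labels[v]
        states = state_sets[label]
        if not states:
            raise ValueError(f"empty state set at node {label}")
        if len(states) == 1:
            assigned[label] = next(iter(states))
        elif policy == "inherit_parent" and v != tree.root:
            pstate = assigned[tree.labels[tree.parent[v]]]
            assigned[label] = pstate if pstate in states else None
        else:
            assigned[label] = None
    return assigned


def enumerate_transitions(
    assignments: dict[str, int | None],
    tree: Phylogeny,
    ingroup: list[str] | None = None,
    state_sets: dict[str, frozenset[int]] | None = None,
) -> list[TransitionRecord]:
    """One record per branch whose two assigned endpoints differ.

    Branches with an unassigned endpoint contribute nothing (the
    minimum-transition convention).  With ``ingroup`` (a list of tip names),
    only branches inside that clade are counted — including the branch
    subtending the clade's root, so a change at the origin of the ingroup is
    attributed to it.
    """
    allowed: set[int] | None = None
    if ingroup is not None:
        allowed = tree.subtree_nodes(tree.mrca(ingroup))
    records: list[TransitionRecord] = []
    for v in tree.preorder:
        if v == tree.root:
            continue
        if allowed is not None and v not in allowed:
            continue
        child = tree.labels[v]
        parent = tree.labels[tree.parent[v]]
        a, b = assignments[parent], assignments[child]
        if a is None or b is None or a == b:
            continue
        resolved = True
        if state_sets is not None:
            resolved = len(state_sets[parent]) == 1 and len(state_sets[child]) == 1
        records.append(TransitionRecord(parent, child, a, b, resolved))
    return records


def build_transition_matrix(
    records: list[TransitionRecord], state_space: list[int] | None = None
) -> TransitionMatrix:
    """Cross-tabulate transition records into a from x to count matrix."""
    if state_space is None:
        codes = sorted(
            {r.from_state for r in records} | {r.to_state for r in records}
        )
    else:
        codes = list(state_space)
    counts = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    for r in records:
        counts.loc[r.from_state, r.to_state] += 1
    return TransitionMatrix(counts)


def origins_of_state(matrix: TransitionMatrix, state: int) -> int:
    """Number of independent derivations of ``state`` (column sum into it)."""
    if state not in matrix.counts.columns:
        raise ValueError(f"state {state} not in transition matrix")
    return int(matrix.counts[state].sum())


def sources_from_state(matrix: TransitionMatrix, state: int) -> int:
    """Number of transitions originating from ``state`` (row sum)."""
    if state not in matrix.counts.index:
        raise ValueError(f"state {state} not in transition matrix")
    return int(matrix.counts.loc[state].sum())


def records_to_frame(records: list[TransitionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent_id": r.parent_id,
                "child_id": r.child_id,
                "from_state": r.from_state,
                "from_label": state_label(r.from_state),
                "to_state": r.to_state,
                "to_label": state_label(r.to_state),
                "resolved": r.resolved,
            }
            for r in records
        ],
        columns=[
            "parent_id", "child_id", "from_state", "from_label",
            "to_state", "to_label", "resolved",
        ],
    )


def write_transition_matrix(matrix: TransitionMatrix, path: str | Path) -> None:
    matrix.labeled().to_csv(path)


# ---------------------------------------------------------------------------
# Bundled study fixture: the published 17-transition table
# ---------------------------------------------------------------------------

def _fixture_frame() -> pd.DataFrame:
    with resources.files("habitevol.data").joinpath("table2_counts.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2_records() -> list[TransitionRecord]:
    """The study's 17 life-habit transitions, one record per event.

    Branch ids are synthetic (``t2_<i>``): the published table reports counts
    by class pair, not branch identities.
    """
    records: list[TransitionRecord] = []
    i = 0
    for _, row in _fixture_frame().iterrows():
        for _ in range(int(row["count"])):
            records.append(
                TransitionRecord(
                    parent_id=f"t2_{i}_anc",
                    child_id=f"t2_{i}_desc",
                    from_state=int(row["from_code"]),
                    to_state=int(row["to_code"]),
                )
            )
            i += 1
    return records


def load_table2_matrix() -> TransitionMatrix:
    """The study's transition-count matrix over all six life-habit classes."""
    return build_transition_matrix(load_table2_records(), state_space=[1, 2, 3, 4, 5, 6])
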