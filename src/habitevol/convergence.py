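"""Classify repeated origins of a derived state as parallel or convergent.

Phylogenetically, two independent origins of the same derived character state
are *parallel* when their lineages started from the same ancestral state and
*convergent* when they started from different ancestral states.  Each
transition record is one origin of its derived state, with the ancestral
state read off the parent end of the branch on which the derived state first
appears.  Because a state with three or more origins can mix both patterns
(the study's gliding scallops arose twice from recessing and twice from
byssal-attaching ancestors), classification is done per unordered pair of
origins, with a per-state summary: ``unique`` (one origin), ``parallel`` (all
ancestors identical), ``convergent`` (all ancestors distinct), or ``both``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .io import VALID_CODES, MISSING_CODE, state_label
from .transitions import TransitionRecord


@dataclass(frozen=True)
class OriginEvent:
    """One independent derivation of a state on one branch."""

    derived_state: int
    parent_id: str
    child_id: str
    ancestral_state: int

    def __post_init__(self) -> None:
        if self.ancestral_state == self.derived_state:
            raise ValueError("ancestral and derived state must differ")


@dataclass
class OriginClassification:
    """All origins of one derived state with pairwise parallel/convergent labels."""

    derived_state: int
    origins: list[OriginEvent]
    pair_labels: list[tuple[int, int, str]]  # (origin index, origin index, label)
    summary: str  # unique | parallel | convergent | both

    @property
    def count(self) -> int:
        return len(self.origins)


def collect_origins(
    records: list[TransitionRecord],
) -> dict[int, list[OriginEvent]]:
    """Group transition records by derived (to) state."""
    out: dict[int, list[OriginEvent]] = {}
    for r in records:
        out.setdefault(r.to_state, []).append(
            OriginEvent(
                derived_state=r.to_state,
                parent_id=r.parent_id,
                child_id=r.child_id,
                ancestral_state=r.from_state,
            )
        )
    return out


def classify(origins: dict[int, list[OriginEvent]]) -> list[OriginClassification]:
    """Label each unordered pair of origins of a state parallel or convergent."""
    out: list[OriginClassification] = []
    for state in sorted(origins):
        evs = origins[state]
        pairs: list[tuple[int, int, str]] = []
        for i, j in combinations(range(len(evs)), 2):
            label = (
                "parallel"
                if evs[i].ancestral_state == evs[j].ancestral_state
                else "convergent"
            )
            pairs.append((i, j, label))
        if len(evs) == 1:
            summary = "unique"
        else:
            labels = {lab for _, _, lab in pairs}
            summary = labels.pop() if len(labels) == 1 else "both"
        out.append(
            OriginClassification(
                derived_state=state, origins=evs, pair_labels=pairs, summary=summary
            )
        )
    return out


def count_parallel_from_state(
    classifications: list[OriginClassification],
    ancestral_state: int,
    include_singletons: bool = True,
) -> int:
    """Number of origin events arising from ``ancestral_state``.

    With ``include_singletons`` (default) every origin from that ancestor
    counts — the row-sum arithmetic behind the study's "12 of 17 (70%)
    transitions from byssate ancestors were parallel".  With it off, an
    origin counts only when its derived state has at least one other origin
    sharing the same ancestor (a strict reading of "parallel").
    """
    if ancestral_state == MISSING_CODE or ancestral_state not in VALID_CODES:
        raise ValueError(f"unknown ancestral state {ancestral_state}")
    total = 0
    for cls in classifications:
        from_a = [e for e in cls.origins if e.ancestral_state == ancestral_state]
        if include_singletons:
            total += len(from_a)
        elif len(from_a) >= 2:
            total += len(from_a)
    return total


def classification_report(classifications: list[OriginClassification]) -> dict:
    """JSON-friendly report: per derived state, origins, ancestors, labels."""
    report = {}
    for cls in classifications:
        report[state_label(cls.derived_state)] = {
            "derived_state": cls.derived_state,
            "n_origins": cls.count,
            "ancestral_states": [e.ancestral_state for e in cls.origins],
            "ancestral_labels": [state_label(e.ancestral_state) for e in cls.origins],
            "origin_branches": [
                [e.parent_id, e.child_id] for e in cls.origins
            ],
            "pair_labels": [
                {"pair": [i, j], "label": lab} for i, j, lab in cls.pair_labels
            ],
            "summary": cls.summary,
        }
    return report
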