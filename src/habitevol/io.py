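"""Domain types and file I/O: rooted phylogenies, categorical character matrices.

The character of interest is the adult life habit of a species, coded as an
integer category::

    0  unknown behaviour (treated as missing data)
    1  cementing
    2  byssal attaching
    3  free-living
    4  recessing
    5  gliding
    6  nestling

Trees are read from Newick (via dendropy) into a light array-backed
:class:`Phylogeny`; character matrices from two-column CSV or a NEXUS data
block into :class:`CharacterMatrix`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CODE = 0

LIFE_HABIT_LABELS: dict[int, str] = {
    0: "unknown",
    1: "cementing",
    2: "byssal",
    3: "free-living",
    4: "recessing",
    5: "gliding",
    6: "nestling",
}

VALID_CODES = frozenset(LIFE_HABIT_LABELS)

#: default clamp for zero/absent branch lengths in likelihood computations
DEFAULT_MIN_BRANCH_LENGTH = 1e-8


def state_label(code: int) -> str:
    """Human-readable name of a state code (falls back to the number itself)."""
    return LIFE_HABIT_LABELS.get(code, str(code))


def normalize_taxon(name: str) -> str:
    """Canonical taxon name: trimmed, internal whitespace collapsed to '_'."""
    return re.sub(r"\s+", "_", str(name).strip())


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Phylogeny:
    """A rooted phylogeny with branch lengths; multifurcations permitted.

    Nodes are integer-indexed; ``labels[i]`` is the taxon name for tips and a
    stable synthetic id (``N<i>``) for internal nodes.  ``lengths[i]`` is the
    length of the branch subtending node ``i`` (0.0 on the root).
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ):
        n = len(children)
        if not (len(lengths) == n and len(labels) == n):
            raise ValueError("children, lengths and labels must have equal length")
        self.children: list[tuple[int, ...]] = [tuple(c) for c in children]
        self.parent = np.full(n, -1, dtype=int)
        for v, ch in enumerate(self.children):
            for c in ch:
                if self.parent[c] != -1:
                    raise ValueError(f"node {c} has two parents")
                self.parent[c] = v
        roots = [v for v in range(n) if self.parent[v] == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        self.lengths = np.asarray(lengths, dtype=float)
        if not np.all(np.isfinite(self.lengths[np.arange(n) != self.root])):
            raise ValueError("branch lengths must be finite")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")

        self.labels: list[str] = []
        seen_tips: set[str] = set()
        for v in range(n):
            lab = labels[v]
            if not self.children[v]:  # tip
                if lab is None or lab == "":
                    raise ValueError(f"tip node {v} has no label")
                lab = normalize_taxon(lab)
                if lab in seen_tips:
                    raise ValueError(f"duplicate tip name: {lab!r}")
                seen_tips.add(lab)
            elif lab is None or lab == "":
                lab = f"N{v}"
            self.labels.append(lab)
        if len(set(self.labels)) != n:
            raise ValueError("node labels not unique")
        self._index = {lab: v for v, lab in enumerate(self.labels)}

        # postorder / preorder once, iteratively (trees may be deep)
        post: list[int] = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                post.append(v)
            else:
                stack.append((v, True))
                for c in self.children[v]:
                    stack.append((c, False))
        self.postorder: tuple[int, ...] = tuple(post)
        self.preorder: tuple[int, ...] = tuple(reversed(post))

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def tip_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def internal_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    @property
    def tip_names(self) -> set[str]:
        return {self.labels[v] for v in self.tip_indices}

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def clamped_lengths(self, min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH) -> np.ndarray:
        """Branch lengths with zeros/NaNs replaced by ``min_branch_length``.

        The root's (meaningless) subtending length is left at 0.
        """
        out = self.lengths.copy()
        bad = ~np.isfinite(out) | (out < min_branch_length)
        bad[self.root] = False
        out[bad] = min_branch_length
        out[self.root] = 0.0
        return out

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.lengths[v]
        return float(max(depth[t] for t in self.tip_indices))

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (root branch excluded)."""
        mask = np.arange(self.n_nodes) != self.root
        return float(np.nansum(self.lengths[mask]))

    def mrca(self, taxa: Iterable[str]) -> int:
        """Index of the most recent common ancestor of the given tip names."""
        targets = {self.index_of(normalize_taxon(t)) for t in taxa}
        if not targets:
            raise ValueError("empty taxon set")
        counts = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder:
            counts[v] += int(v in targets)
            for c in self.children[v]:
                counts[v] += counts[c]
        want = len(targets)
        for v in self.postorder:  # first postorder node covering all = MRCA
            if counts[v] == want:
                return v
        raise AssertionError("unreachable")

    def subtree_nodes(self, v: int) -> set[int]:
        """All node indices in the clade rooted at ``v`` (inclusive)."""
        out: set[int] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            out.add(u)
            stack.extend(self.children[u])
        return out

    # -- Newick ------------------------------------------------------------
    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self.postorder:
            if self.is_tip(v):
                s = self.labels[v]
            else:
                s = "(" + ",".join(parts[c] for c in self.children[v]) + ")"
            if v != self.root:
                s += f":{self.lengths[v]:.10g}"
            parts[v] = s
        return parts[self.root] + ";"

    def __repr__(self) -> str:
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


def _from_dendropy(dtree: dendropy.Tree) -> tuple[list[list[int]], list[float], list[str | None], int]:
    """Flatten a dendropy tree into (children, lengths, labels); returns n_clamped=missing/zero count."""
    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    children: list[list[int]] = [[] for _ in dnodes]
    lengths: list[float] = [0.0] * len(dnodes)
    labels: list[str | None] = [None] * len(dnodes)
    for nd in dnodes:
        i = index[id(nd)]
        for ch in nd.child_nodes():
            children[i].append(index[id(ch)])
        lengths[i] = float(nd.edge.length) if nd.edge.length is not None else float("nan")
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    n_missing = sum(
        1
        for i, nd in enumerate(dnodes)
        if i != 0 and (not np.isfinite(lengths[i]) or lengths[i] <= 0.0)
    )
    return children, lengths, labels, n_missing


def read_newick(
    path: str | Path,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
) -> Phylogeny:
    """Read a rooted tree from a Newick file.

    Zero or absent branch lengths are clamped to ``min_branch_length`` (the Mk
    transition matrix is singular only at exactly 0, and consensus trees often
    carry near-zero branches); the number of clamped branches is logged.
    Duplicate tip names and malformed Newick raise errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tree file not found: {path}")
    text = path.read_text()
    return parse_newick(text, min_branch_length=min_branch_length)


def parse_newick(
    newick: str,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny` (see :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        col = getattr(exc, "col_num", None)
        pos = f" near character {col}" if col is not None else ""
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc
    children, lengths, labels, n_clamped = _from_dendropy(dtree)
    n = len(children)
    neg = [i for i in range(1, n) if np.isfinite(lengths[i]) and lengths[i] < 0]
    if neg:
        raise ValueError(f"branch lengths must be non-negative ({len(neg)} negative)")
    clamped = [
        min_branch_length if (i != 0 and (not np.isfinite(lengths[i]) or lengths[i] < min_branch_length)) else lengths[i]
        for i in range(n)
    ]
    clamped[0] = 0.0
    if n_clamped:
        logger.warning(
            "clamped %d zero/absent branch lengths to %g", n_clamped, min_branch_length
        )
    return Phylogeny(children, clamped, labels)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxon -> coded life-habit state; code 0 means unknown/missing.

    ``state_space`` is the ordered list of distinct non-missing codes present,
    of size ``k``.  Code 0 never enters the state space and is never
    reconstructed.
    """

    entries: dict[str, int]
    state_space: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.entries.items() if c not in VALID_CODES}
        if bad:
            raise ValueError(f"invalid state codes (must be 0-6): {bad}")
        if not self.state_space:
            self.state_space = sorted(
                {c for c in self.entries.values() if c != MISSING_CODE}
            )
        if MISSING_CODE in self.state_space:
            raise ValueError("state_space must not contain the missing code 0")

    @classmethod
    def from_dict(cls, entries: Mapping[str, int]) -> "CharacterMatrix":
        return cls({normalize_taxon(t): int(c) for t, c in entries.items()})

    @property
    def k(self) -> int:
        return len(self.state_space)

    @property
    def taxa(self) -> set[str]:
        return set(self.entries)

    @property
    def missing_taxa(self) -> set[str]:
        return {t for t, c in self.entries.items() if c == MISSING_CODE}

    def validate_against(self, tree: Phylogeny) -> "CharacterMatrix":
        """Return a matrix restricted to the tree's tips; error if any tip lacks data."""
        tips = tree.tip_names
        missing = sorted(tips - self.taxa)
        if missing:
            raise ValueError(f"no character entry for tree tips: {missing}")
        extra = sorted(self.taxa - tips)
        if extra:
            logger.warning("dropping %d taxa absent from tree: %s", len(extra), extra)
        return CharacterMatrix({t: self.entries[t] for t in tips})


def read_character_matrix(
    path: str | Path, tree: Phylogeny | None = None
) -> CharacterMatrix:
    """Read a character matrix from CSV (columns taxon,state_code) or NEXUS.

    If a tree is given the matrix is validated against its tip set: every tip
    must have an entry; taxa absent from the tree are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"character matrix file not found: {path}")
    head = path.read_text(errors="replace").lstrip()[:6].upper()
    if head.startswith("#NEXUS"):
        cm = _read_nexus_matrix(path)
    else:
        cm = _read_csv_matrix(path)
    if tree is not None:
        cm = cm.validate_against(tree)
    return cm


def _read_csv_matrix(path: Path) -> CharacterMatrix:
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "taxon" not in cols or "state_code" not in cols:
        raise ValueError("character CSV must have columns 'taxon' and 'state_code'")
    entries: dict[str, int] = {}
    for _, row in df.iterrows():
        taxon = normalize_taxon(row[cols["taxon"]])
        if taxon in entries:
            raise ValueError(f"duplicate taxon in character matrix: {taxon!r}")
        entries[taxon] = int(row[cols["state_code"]])
    return CharacterMatrix(entries)


def _read_nexus_matrix(path: Path) -> CharacterMatrix:
    dm = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
    entries: dict[str, int] = {}
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        if len(seq) < 1:
            raise ValueError(f"no character for taxon {taxon.label!r}")
        sym = str(seq[0].symbol if hasattr(seq[0], "symbol") else seq[0])
        if sym in ("?", "-"):
            code = MISSING_CODE
        else:
            try:
                code = int(sym)
            except ValueError as exc:
                raise ValueError(
                    f"non-integer state {sym!r} for taxon {taxon.label!r}"
                ) from exc
        entries[normalize_taxon(taxon.label)] = code
    return CharacterMatrix(entries)


def write_character_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {"taxon": list(matrix.entries), "state_code": list(matrix.entries.values())}
    )
    df.to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """Knobs shared across the pipeline.

    lnl_threshold
        Log-likelihood difference above which the worse state at a node is
        rejected; differences of exactly the threshold or less leave the node
        ambiguous.
    ambiguity_policy
        How ambiguous nodes are assigned when counting transitions:
        ``inherit_parent`` (take the parent's state when compatible, yielding
        a minimal transition count) or ``skip_branch`` (leave unassigned).
    """

    lnl_threshold: float = 2.0
    ambiguity_policy: str = "inherit_parent"
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH
    rng_seed: int = 0
    ingroup_clade: list[str] | None = None

    def __post_init__(self) -> None:
        if self.lnl_threshold <= 0:
            raise ValueError("lnl_threshold must be > 0")
        if self.min_branch_length <= 0:
            raise ValueError("min_branch_length must be > 0")
        if self.ambiguity_policy not in ("inherit_parent", "skip_branch"):
            raise ValueError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")
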