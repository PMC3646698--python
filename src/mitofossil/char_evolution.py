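"""Gain/loss reconstruction of binary characters on a fixed rooted tree.

Two parsimony variants are provided:

* **Dollo parsimony** — at most one gain per character (appropriate for RNA
  editing sites, where parallel origin of the same site is implausible); the
  gain is placed on the branch above the MRCA of all taxa observed in state 1
  and losses are placed on the minimal set of branches explaining every
  observed absence below it.
* **Unordered (Fitch) parsimony** — no asymmetry between gain and loss
  (used for plastid-derived tRNA presence/absence), implemented as a
  Sankoff-style dynamic program that also counts the number of equally
  parsimonious labelings so ties are flagged exactly.

Missing data ('?') constrains nothing: a '?' leaf may be assigned either
state, and subtrees containing only '?' leaves receive no events.  A
brute-force enumerator over all internal-state assignments serves as an
independent oracle for small trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .core_io import DatedTree
from .edit_calling import EditMatrix

GAIN = "gain"
LOSS = "loss"

_STATES = {"0", "1", "?"}


def _check_column(tree: DatedTree, column: dict[str, str]) -> dict[int, str]:
    """Map leaf labels to node ids, validating states."""
    out = {}
    for leaf in tree.leaves:
        label = tree.nodes[leaf].label
        if label not in column:
            raise ValueError(f"leaf {label!r} missing from column")
        state = column[label]
        if state not in _STATES:
            raise ValueError(f"state {state!r} for {label!r} not in 0/1/?")
        out[leaf] = state
    extra = set(column) - set(tree.leaf_labels)
    if extra:
        raise ValueError(f"column taxa not on tree: {sorted(extra)}")
    return out


@dataclass
class DolloResult:
    """Single-character Dollo reconstruction."""

    gain_node: int | None  # node whose parent-branch carries the gain; may be root
    loss_branches: list[int] = field(default_factory=list)
    ambiguous: bool = False  # gain sits on a root-adjacent branch

    @property
    def n_gains(self) -> int:
        return 0 if self.gain_node is None else 1

    @property
    def n_events(self) -> int:
        return self.n_gains + len(self.loss_branches)


def dollo_reconstruct(tree: DatedTree, column: dict[str, str]) -> DolloResult:
    """Most-parsimonious single-gain scenario for one 0/1/? character.

    Returns zero events when no leaf is observed in state 1.  The gain is
    ambiguous (flagged) when it falls on a branch adjacent to the root: the
    character could equally have been present ancestrally and lost on the
    sister branch, which parsimony cannot distinguish.
    """
    states = _check_column(tree, column)
    ones = [v for v, s in states.items() if s == "1"]
    if not ones:
        return DolloResult(None)
    gain_node = tree.mrca(ones)

    # bottom-up labels within the gain subtree: zero / one / mixed / none
    label: dict[int, str] = {}
    for v in tree.postorder():
        node = tree.nodes[v]
        if not node.children:
            s = states[v]
            label[v] = {"1": "one", "0": "zero", "?": "none"}[s]
        else:
            kids = [label[c] for c in node.children if label[c] != "none"]
            if not kids:
                label[v] = "none"
            elif all(k == "zero" for k in kids):
                label[v] = "zero"
            elif all(k == "one" for k in kids):
                label[v] = "one"
            else:
                label[v] = "mixed"

    losses: list[int] = []
    stack = [gain_node]
    while stack:
        v = stack.pop()
        for c in tree.nodes[v].children:
            if label[c] == "zero":
                losses.append(c)
            elif label[c] == "mixed":
                stack.append(c)
            # 'one' subtrees need no events below; 'none' subtrees get none
    ambiguous = tree.nodes[gain_node].parent == tree.root
    return DolloResult(gain_node, sorted(losses), ambiguous)


@dataclass
class FitchResult:
    """Unordered-parsimony reconstruction of one character."""

    n_changes: int
    events: dict[int, str]  # branch (child node id) -> 'gain' | 'loss'
    tie: bool  # multiple equally parsimonious labelings exist
    states: dict[int, int]  # the returned labeling, per node id


def fitch_reconstruct(tree: DatedTree, column: dict[str, str]) -> FitchResult:
    """Minimum unordered changes with '?' treated as {0, 1}.

    One most-parsimonious labeling is returned deterministically: state 0 is
    preferred at the root, and each child takes its parent's state whenever
    that is optimal.  ``tie`` is exact, from counting optimal labelings.
    """
    states = _check_column(tree, column)
    INF = 10**9
    cost = np.zeros((len(tree.nodes), 2), dtype=np.int64)
    num = np.zeros((len(tree.nodes), 2), dtype=np.float64)
    for v in tree.postorder():
        node = tree.nodes[v]
        if not node.children:
            s = states[v]
            for st in (0, 1):
                allowed = s == "?" or int(s) == st
                cost[v, st] = 0 if allowed else INF
                num[v, st] = 1.0 if allowed else 0.0
        else:
            for st in (0, 1):
                total, ways = 0, 1.0
                for c in node.children:
                    same, diff = cost[c, st], cost[c, 1 - st] + 1
                    best = min(same, diff)
                    total += best
                    w = (num[c, st] if same == best else 0.0) + (
                        num[c, 1 - st] if diff == best else 0.0
                    )
                    ways *= w
                cost[v, st] = total
                num[v, st] = ways
    root = tree.root
    n_changes = int(cost[root].min())
    n_opt = sum(float(num[root, st]) for st in (0, 1) if cost[root, st] == n_changes)
    tie = n_opt > 1.0

    assign: dict[int, int] = {}
    assign[root] = 0 if cost[root, 0] == n_changes else 1
    for v in tree.preorder():
        if v == root:
            continue
        p = assign[tree.nodes[v].parent]
        same, diff = cost[v, p], cost[v, 1 - p] + 1
        assign[v] = p if same <= diff else 1 - p
    events = {}
    for v in tree.branch_ids():
        p = assign[tree.nodes[v].parent]
        if assign[v] != p:
            events[v] = GAIN if assign[v] == 1 else LOSS
    return FitchResult(n_changes, events, tie, assign)


# ---------------------------------------------------------------------------
# Brute-force oracle


@lru_cache(maxsize=32)
def _bit_patterns(k: int) -> np.ndarray:
    """All 2^k binary assignments as a (2^k, k) uint8 array."""
    if k == 0:
        return np.zeros((1, 0), dtype=np.uint8)
    grid = np.indices((2,) * k).reshape(k, -1).T
    return grid.astype(np.uint8)


def brute_force_min_events(
    tree: DatedTree, column: dict[str, str], constraint: str = "dollo"
) -> int:
    """Exhaustive minimum event count over all node-state assignments.

    For ``constraint="dollo"`` an assignment is valid when it implies at most
    one gain, counting presence at the root itself as the single gain; the
    returned minimum is gains + losses.  For ``constraint="unordered"`` it is
    the plain minimum number of state changes.  '?' leaves are free.  Guarded
    to trees with at most 12 leaves.
    """
    if constraint not in ("dollo", "unordered"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if len(tree.leaves) > 12:
        raise ValueError("brute force limited to 12 leaves")
    states = _check_column(tree, column)
    fixed = {v: int(s) for v, s in states.items() if s != "?"}
    free = [n.id for n in tree.nodes if n.children or states[n.id] == "?"]
    patterns = _bit_patterns(len(free))
    full = np.zeros((len(patterns), len(tree.nodes)), dtype=np.uint8)
    for v, s in fixed.items():
        full[:, v] = s
    full[:, free] = patterns

    branch_ids = tree.branch_ids()
    parents = np.array([tree.nodes[v].parent for v in branch_ids])
    children = np.array(branch_ids)
    pa, ch = full[:, parents], full[:, children]
    gains = ((pa == 0) & (ch == 1)).sum(axis=1)
    losses = ((pa == 1) & (ch == 0)).sum(axis=1)
    if constraint == "unordered":
        return int((gains + losses).min())
    gains_total = gains + full[:, tree.root]
    valid = gains_total <= 1
    return int((gains_total + losses)[valid].min())


# ---------------------------------------------------------------------------
# Matrix-level tally


@dataclass
class BranchEventTable:
    """Per-branch gain/loss totals summed over the characters of a matrix."""

    tree: DatedTree
    gains: dict[int, int]
    losses: dict[int, int]
    root_gains: int = 0
    ambiguous_sites: list[str] = field(default_factory=list)
    n_sites: int = 0

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values()) + self.root_gains

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.tree.branch_ids():
            node = self.tree.nodes[v]
            rows.append(
                {
                    "branch_id": v,
                    "parent": node.parent,
                    "child": v,
                    "label": node.label or "",
                    "gains": self.gains.get(v, 0),
                    "losses": self.losses.get(v, 0),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def dollo_tally(
    tree: DatedTree, matrix: EditMatrix, partition: str = "all"
) -> BranchEventTable:
    """Sum Dollo reconstructions over the sites of an edit matrix.

    ``partition`` selects 'all' sites, or only those labeled 'synonymous' /
    'nonsynonymous' by the partition filter.  Tree leaves absent from the
    matrix are treated as missing data.  Characters whose gain lands on a
    root-adjacent branch are counted there and reported as ambiguous: the
    site could equally be ancestral, lost on the sister lineage.
    """
    if matrix.n_sites() == 0:
        raise ValueError("empty edit matrix")
    extra = set(matrix.taxa) - set(tree.leaf_labels)
    if extra:
        raise ValueError(f"matrix taxa not on tree: {sorted(extra)}")
    site_ids = matrix.site_ids(partition)
    gains: dict[int, int] = {}
    losses: dict[int, int] = {}
    root_gains = 0
    ambiguous: list[str] = []
    labels = tree.leaf_labels
    for site_id in site_ids:
        cells = matrix.column(site_id)
        column = {lab: cells.get(lab, "?") for lab in labels}
        res = dollo_reconstruct(tree, column)
        if res.gain_node is None:
            continue
        if res.gain_node == tree.root:
            root_gains += 1
        else:
            gains[res.gain_node] = gains.get(res.gain_node, 0) + 1
        for b in res.loss_branches:
            losses[b] = losses.get(b, 0) + 1
        if res.ambiguous:
            ambiguous.append(site_id)
    return BranchEventTable(tree, gains, losses, root_gains, ambiguous, len(site_ids))
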