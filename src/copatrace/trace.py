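"""Evolutionary trace (ET) analysis.

Classic integer-rank ET: partition the sequence tree into k groups by
cutting its earliest-diverging nodes, and rank each alignment column by the
smallest k at which every group becomes internally invariant at that column.
Low-rank columns mark residues conserved throughout the family's history --
the working assumption being that active-site residues are under the
strongest constraint.  Class-specific columns (invariant within each of two
top-level groups but different between them) are the raw material for the
group-diagnostic metal-binding motifs used in screening.

Gaps count as a distinct symbol that breaks invariance (conservative for
motif calling).  The tree is midpoint-rooted for node ordering; internal
nodes are ordered by edge depth from the root with ties broken by the
lexicographically smallest contained leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

from .align_phylo import GAP, MultipleAlignment

UNRANKED = 0  # sentinel; real ranks start at 1


@dataclass(frozen=True)
class TracePartition:
    k: int
    groups: tuple[frozenset[str], ...]


@dataclass
class TraceColumn:
    column: int
    rank: int  # UNRANKED when never invariant up to max_rank
    group_consensus: dict[str, str] = field(default_factory=dict)
    is_class_specific: bool = False


@dataclass
class TraceResult:
    columns: list[TraceColumn]
    msa: MultipleAlignment
    tree: TreeNode
    max_rank: int

    def ranked(self, cutoff: int) -> list[TraceColumn]:
        return [c for c in self.columns if c.rank != UNRANKED and c.rank <= cutoff]


def _rooted_copy(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted deep copy; already-rooted (2-child) trees are kept."""
    t = tree.copy()
    if len(t.children) == 2:
        return t
    return t.root_at_midpoint()


def _depth(node: TreeNode) -> int:
    d = 0
    p = node
    while p.parent is not None:
        d += 1
        p = p.parent
    return d


def _tip_names(node: TreeNode):
    if node.is_tip():
        yield node.name
    else:
        for t in node.tips():
            yield t.name


def _min_leaf(nodes: list[TreeNode]) -> str:
    return min(nm for n in nodes for nm in _tip_names(n))


def partition_tree(tree: TreeNode, k: int) -> TracePartition:
    """Cut the midpoint-rooted tree at its earliest-diverging nodes, yielding
    exactly k monophyletic groups.

    Groups are grown by repeated binary splits: at each step, the group whose
    defining node diverges earliest (smallest edge depth from the root, ties
    by smallest contained leaf name) is split.  Binary nodes split into their
    two child clades; multifurcations are peeled one child at a time,
    smallest leaf name first, so every step adds exactly one group.
    """
    root = _rooted_copy(tree)
    leaves = frozenset(t.name for t in root.tips())
    n = len(leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    # a group is a list of sibling subtree roots; its leaf set is the union
    groups: list[list[TreeNode]] = [[root]]

    def priority(entry: list[TreeNode]) -> tuple[int, str]:
        if len(entry) == 1:
            return (_depth(entry[0]), _min_leaf(entry))
        return (_depth(entry[0]) - 1, _min_leaf(entry))

    def splittable(entry: list[TreeNode]) -> bool:
        return len(entry) > 1 or not entry[0].is_tip()

    for _ in range(k - 1):
        candidates = [
            (priority(g), i) for i, g in enumerate(groups) if splittable(g)
        ]
        if not candidates:
            raise ValueError(f"could not partition tree into exactly {k} groups")
        _, idx = min(candidates)
        entry = groups[idx]
        if len(entry) == 1:
            parts = sorted(entry[0].children, key=lambda c: _min_leaf([c]))
        else:
            parts = sorted(entry, key=lambda c: _min_leaf([c]))
        if len(parts) == 2:
            first, rest = [parts[0]], [parts[1]]
        else:
            first, rest = [parts[0]], parts[1:]
        groups = groups[:idx] + [first, rest] + groups[idx + 1 :]

    leaf_groups = tuple(
        frozenset(nm for node in g for nm in _tip_names(node)) for g in groups
    )
    return TracePartition(k=k, groups=leaf_groups)


def _invariant(msa: MultipleAlignment, group: frozenset[str], col: int) -> str | None:
    """The shared symbol of *group* at *col*, or None if variable.  A gap is
    a symbol of its own; an all-gap group is 'invariant' at the gap symbol."""
    symbols = {msa.row(name)[col] for name in group}
    if len(symbols) == 1:
        return next(iter(symbols))
    return None


def trace_ranks(
    msa: MultipleAlignment,
    tree: TreeNode,
    max_rank: int | None = None,
) -> TraceResult:
    """Integer ET ranks for every alignment column.

    The rank of a column is the smallest k <= max_rank such that the column
    is invariant within every group of the k-group partition; columns still
    variable at max_rank get UNRANKED.
    """
    tree_leaves = {t.name for t in tree.tips()}
    if set(msa.names) != tree_leaves:
        raise ValueError(
            f"alignment names and tree leaves differ: "
            f"{sorted(set(msa.names) ^ tree_leaves)}"
        )
    n = len(msa.names)
    if max_rank is None:
        max_rank = n
    max_rank = min(max_rank, n)

    columns = [TraceColumn(column=c, rank=UNRANKED) for c in range(msa.n_cols)]
    unresolved = set(range(msa.n_cols))
    for k in range(1, max_rank + 1):
        part = partition_tree(tree, k)
        for c in sorted(unresolved):
            consensus: dict[str, str] = {}
            ok = True
            for gi, group in enumerate(part.groups):
                sym = _invariant(msa, group, c)
                if sym is None:
                    ok = False
                    break
                consensus[f"g{gi + 1}"] = sym
            if ok:
                columns[c].rank = k
                columns[c].group_consensus = consensus
        unresolved -= {c for c in unresolved if columns[c].rank != UNRANKED}
        if not unresolved:
            break
    return TraceResult(columns=columns, msa=msa, tree=tree, max_rank=max_rank)


def class_specific_columns(
    trace: TraceResult, partition_k2: TracePartition
) -> list[TraceColumn]:
    """Columns invariant within each of two groups but differing between
    them: the group-diagnostic residues."""
    if partition_k2.k != 2:
        raise ValueError("class-specific analysis requires a 2-group partition")
    g1, g2 = partition_k2.groups
    out = []
    for col in trace.columns:
        a = _invariant(trace.msa, g1, col.column)
        b = _invariant(trace.msa, g2, col.column)
        if a is not None and b is not None and a != b and GAP not in (a, b):
            col.is_class_specific = True
            col.group_consensus = {"g1": a, "g2": b}
            out.append(col)
    return out


def _group_consensus_residue(
    msa: MultipleAlignment, group: frozenset[str], col: int
) -> str:
    """Most frequent symbol of the group at the column (ties by residue)."""
    counts: dict[str, int] = {}
    for name in group:
        ch = msa.row(name)[col]
        counts[ch] = counts.get(ch, 0) + 1
    return max(counts, key=lambda ch: (counts[ch], ch))


def _pattern_matches(text: str, pattern: str) -> list[int]:
    hits = []
    for i in range(len(text) - len(pattern) + 1):
        ok = True
        for p, t in zip(pattern, text[i : i + len(pattern)]):
            if t == "X":
                ok = False  # unknown residues never satisfy a position
                break
            if p != "X" and p != t:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


@dataclass(frozen=True)
class MotifWindow:
    pattern: str
    group: str
    columns: tuple[int, ...]
    text: str


def motif_columns(
    trace: TraceResult,
    msa: MultipleAlignment,
    patterns: list,
    rank_cutoff: int = 3,
    partition: TracePartition | None = None,
) -> dict[str, list[MotifWindow]]:
    """Locate motif patterns in the per-group consensus over traced columns.

    For each group of *partition* (default: the 2-group partition of the
    trace's tree), the conserved columns for that group -- columns invariant
    within the group, plus any column with global rank <= rank_cutoff -- have
    their group-consensus residues concatenated (gap columns skipped) and
    scanned for each pattern; matches are reported as the MSA columns they
    occupy.  Class-specific motifs are invariant in their own group but not
    globally, which is why group-level invariance matters here.
    """
    if partition is None:
        partition = partition_tree(trace.tree, 2)
    globally_ranked = {c.column for c in trace.ranked(rank_cutoff)}
    out: dict[str, list[MotifWindow]] = {}
    for pat in patterns:
        name = getattr(pat, "name", str(pat))
        pattern = getattr(pat, "pattern", str(pat))
        windows: list[MotifWindow] = []
        for gi, group in enumerate(partition.groups):
            cols, residues = [], []
            for c in range(msa.n_cols):
                if c not in globally_ranked and _invariant(msa, group, c) is None:
                    continue
                ch = _group_consensus_residue(msa, group, c)
                if ch == GAP:
                    continue
                cols.append(c)
                residues.append(ch)
            text = "".join(residues)
            for start in _pattern_matches(text, pattern):
                windows.append(
                    MotifWindow(
                        pattern=name,
                        group=f"g{gi + 1}",
                        columns=tuple(cols[start : start + len(pattern)]),
                        text=text[start : start + len(pattern)],
                    )
                )
        if windows:
            out[name] = windows
    return out
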