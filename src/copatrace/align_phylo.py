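"""Protein alignment and phylogenetics primitives.

Covers pairwise global alignment (Gotoh affine), progressive multiple
alignment over a neighbor-joining guide tree, conserved-block trimming of
alignments before tree building, neighbor-joining tree construction, and
Robinson-Foulds topology comparison.  Progressive profile alignment is a
deliberate, deterministic stand-in for iterative-refinement aligners: a
single pass up the guide tree with position-specific sum-of-pairs scoring,
which is sufficient for the motif-column bookkeeping this package does.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from skbio import TreeNode

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
GAP = "-"


def _load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    m = substitution_matrices.load(name)
    sub = np.zeros((len(PROTEIN_ALPHABET), len(PROTEIN_ALPHABET)))
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            sub[i, j] = m[a, b]
    return sub


_BLOSUM62 = _load_matrix("BLOSUM62")


def _validate_protein(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty sequence: {name}")
    for pos, ch in enumerate(seq):
        if ch not in _AA_INDEX:
            raise ValueError(
                f"invalid residue {ch!r} in {name} at position {pos + 1}"
            )


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the amino-acid alphabet; gaps carry zero
    weight so gappy columns score proportionally less."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, len(PROTEIN_ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                prof[c, _AA_INDEX[ch]] += 1.0
    return prof / len(rows)


def _affine_dp(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, list[str]]:
    """Global affine-gap DP over a precomputed column-score matrix S
    (shape La x Lb).  A gap run of length L costs gap_open + L * gap_extend.

    Returns (score, ops) where ops is the traceback as a list of 'D'
    (diagonal), 'U' (consume A, gap in B), 'L' (consume B, gap in A).
    Tie-breaking prefers diagonal, then up, then left.
    """
    la, lb = S.shape
    NEG = -1e30
    oc = gap_open + gap_extend
    H = np.full((la + 1, lb + 1), NEG)
    E = np.full((la + 1, lb + 1), NEG)  # gap in A (moves j)
    F = np.full((la + 1, lb + 1), NEG)  # gap in B (moves i)
    pH = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 1 diag, 2 up(F), 3 left(E)
    pE = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 1 open, 2 extend
    pF = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for j in range(1, lb + 1):
        E[0, j] = -(gap_open + j * gap_extend)
        H[0, j] = E[0, j]
        pH[0, j] = 3
        pE[0, j] = 2 if j > 1 else 1
    for i in range(1, la + 1):
        F[i, 0] = -(gap_open + i * gap_extend)
        H[i, 0] = F[i, 0]
        pH[i, 0] = 2
        pF[i, 0] = 2 if i > 1 else 1

    Hl, El, Fl = H.tolist(), E.tolist(), F.tolist()
    Sl = S.tolist()
    for i in range(1, la + 1):
        Hi, Hp = Hl[i], Hl[i - 1]
        Ei = El[i]
        Fi, Fp = Fl[i], Fl[i - 1]
        Si = Sl[i - 1]
        pHi, pEi, pFi = pH[i], pE[i], pF[i]
        for j in range(1, lb + 1):
            e_open = Hi[j - 1] - oc
            e_ext = Ei[j - 1] - gap_extend
            if e_open >= e_ext:
                e, pe = e_open, 1
            else:
                e, pe = e_ext, 2
            f_open = Hp[j] - oc
            f_ext = Fp[j] - gap_extend
            if f_open >= f_ext:
                f, pf = f_open, 1
            else:
                f, pf = f_ext, 2
            d = Hp[j - 1] + Si[j - 1]
            # preference on ties: diagonal, then up, then left
            if d >= f and d >= e:
                h, ph = d, 1
            elif f >= e:
                h, ph = f, 2
            else:
                h, ph = e, 3
            Hi[j] = h
            Ei[j] = e
            Fi[j] = f
            pHi[j] = ph
            pEi[j] = pe
            pFi[j] = pf

    score = Hl[la][lb]
    ops: list[str] = []
    i, j, state = la, lb, "H"
    while i > 0 or j > 0:
        if state == "H":
            ph = pH[i, j]
            if ph == 1:
                ops.append("D")
                i -= 1
                j -= 1
            elif ph == 2:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            ops.append("L")
            if pE[i, j] == 1:
                state = "H"
            j -= 1
        else:
            ops.append("U")
            if pF[i, j] == 1:
                state = "H"
            i -= 1
    ops.reverse()
    return float(score), ops


def global_align_pair(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[float, tuple[str, str]]:
    """Optimal global alignment of two proteins under affine gaps.

    A gap run of length L costs ``gap_open + L * gap_extend``.  Traceback is
    deterministic (diagonal preferred over up over left on score ties).
    """
    _validate_protein(a, "first sequence")
    _validate_protein(b, "second sequence")
    sub = _BLOSUM62 if matrix == "BLOSUM62" else _load_matrix(matrix)
    ai = np.array([_AA_INDEX[c] for c in a])
    bi = np.array([_AA_INDEX[c] for c in b])
    S = sub[np.ix_(ai, bi)]
    score, ops = _affine_dp(S, gap_open, gap_extend)
    ra, rb = [], []
    ia = ib = 0
    for op in ops:
        if op == "D":
            ra.append(a[ia])
            rb.append(b[ib])
            ia += 1
            ib += 1
        elif op == "U":
            ra.append(a[ia])
            rb.append(GAP)
            ia += 1
        else:
            ra.append(GAP)
            rb.append(b[ib])
            ib += 1
    return score, ("".join(ra), "".join(rb))


def percent_identity(pair: tuple[str, str]) -> float:
    """Identity over columns where both rows carry a residue, in percent."""
    a, b = pair
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    both = same = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                same += 1
    if both == 0:
        logger.warning("no co-ungapped columns; identity reported as 0")
        return 0.0
    return 100.0 * same / both


@dataclass
class MultipleAlignment:
    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def column(self, c: int) -> str:
        return "".join(r[c] for r in self.rows)

    def subset(self, names: list[str]) -> "MultipleAlignment":
        return MultipleAlignment(list(names), [self.row(n) for n in names])


def read_msa(path) -> MultipleAlignment:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(names, rows)


def write_msa(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: np.ndarray, names: list[str]) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    *D* must be symmetric with zero diagonal, size >= 3.  Ties in the Q
    criterion resolve by the lexicographically smallest (minimum leaf name)
    pair.  Negative branch lengths are clamped to zero with the deficit
    moved to the sister branch, preserving the pair's summed length.
    Returns an unrooted tree (trifurcating root).
    """
    D = np.asarray(D, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    minleaf: list[str] = list(names)
    D = D.copy()
    active = list(range(n))

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                tag = tuple(sorted((minleaf[i], minleaf[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and tag < best[1]
                ):
                    best = (q, tag)
                    best_pair = (i, j)
        i, j = best_pair
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        # grow the matrix with the new node
        k_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(parent)
        minleaf.append(min(minleaf[i], minleaf[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]

    if len(active) == 2:
        i, j = active
        # attach the final pair under a trifurcating-style root; one of them
        # is typically the accumulated internal node
        a, b = nodes[i], nodes[j]
        d = D[i, j]
        if not a.is_tip():
            a, b = a, b
        if not b.is_tip() and a.is_tip():
            a, b = b, a
        if not a.is_tip():
            # splice: hang b off a's root with the remaining distance
            b.length = max(d, 0.0)
            a.append(b)
            root = a
        else:
            a.length = max(d / 2, 0.0)
            b.length = max(d / 2, 0.0)
            root = TreeNode(children=[a, b])
    root.length = None
    return root


def tree_from_additive(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Patristic distance matrix of a tree (test/oracle helper)."""
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    D = np.zeros((n, n))
    dmat = tree.tip_tip_distances()
    for a in range(n):
        for b in range(n):
            if a != b:
                D[a, b] = dmat[tips[a], tips[b]]
    return D, tips


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _merge_alignments(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ _BLOSUM62 @ pb.T
    _, ops = _affine_dp(S, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
        if op in ("D", "L"):
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
        else:
            for r in out_b:
                r.append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(
    seqs: dict[str, str],
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Progressive profile alignment over an NJ guide tree.

    Guide distances are 1 - pid/100 from pairwise global alignments.  The
    guide tree is midpoint-rooted (so the deepest split is crossed last) and
    profile pairs are merged post-order up it with sum-of-pairs scoring.
    Input row order is preserved in the output.
    """
    names = list(seqs)
    if len(names) < 2:
        raise ValueError("nothing to align: need at least 2 sequences")
    for nm in names:
        _validate_protein(seqs[nm], nm)
    if len(names) == 2:
        _, (ra, rb) = global_align_pair(
            seqs[names[0]], seqs[names[1]], gap_open=gap_open, gap_extend=gap_extend
        )
        return MultipleAlignment(names, [ra, rb])

    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, pair = global_align_pair(
                seqs[names[i]], seqs[names[j]], gap_open=gap_open, gap_extend=gap_extend
            )
            D[i, j] = D[j, i] = 1.0 - percent_identity(pair) / 100.0
    guide = nj_tree(D, names).root_at_midpoint()

    def align_node(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqs[node.name]]
        child_results = [align_node(c) for c in node.children]
        nms, rows = child_results[0]
        for nms_b, rows_b in child_results[1:]:
            rows, rows_b = _merge_alignments(rows, rows_b, gap_open, gap_extend)
            nms = nms + nms_b
            rows = rows + rows_b
        return nms, rows

    nms, rows = align_node(guide)
    order = {nm: i for i, nm in enumerate(nms)}
    return MultipleAlignment(names, [rows[order[nm]] for nm in names])


# ---------------------------------------------------------------------------
# conserved-block trimming


@dataclass
class BlockParams:
    min_block_len: int = 10
    max_noncons_run: int = 8
    cons_frac: float = 0.5
    strict_frac: float = 0.85
    max_gap_frac: float = 0.5


@dataclass
class BlockTrimming:
    blocks: list[tuple[int, int]]
    params: BlockParams = field(default_factory=BlockParams)

    @property
    def n_cols_kept(self) -> int:
        return sum(b - a for a, b in self.blocks)


def _column_classes(msa: MultipleAlignment, p: BlockParams):
    """Per column: (gap_ok, conserved, strict)."""
    out = []
    n = msa.n_rows
    for c in range(msa.n_cols):
        col = msa.column(c)
        gaps = col.count(GAP)
        gap_ok = gaps / n <= p.max_gap_frac
        residues = [ch for ch in col if ch != GAP]
        top = max((residues.count(r) for r in set(residues)), default=0)
        conserved = gap_ok and top / n >= p.cons_frac
        strict = gap_ok and top / n >= p.strict_frac
        out.append((gap_ok, conserved, strict))
    return out


def trim_conserved_blocks(
    msa: MultipleAlignment, params: BlockParams | None = None
) -> tuple[BlockTrimming, MultipleAlignment]:
    """Select well-conserved, low-gap alignment blocks.

    Columns failing the gap-fraction cap are never kept; runs of
    non-conserved columns longer than ``max_noncons_run`` break blocks; each
    block is trimmed at both flanks to its outermost strictly conserved
    column; blocks shorter than ``min_block_len`` are dropped.  The trimmed
    alignment concatenates the kept blocks.
    """
    p = params or BlockParams()
    classes = _column_classes(msa, p)
    n = msa.n_cols

    # break at high-gap columns and at long non-conserved runs
    breaks = [False] * n
    for c, (gap_ok, _, _) in enumerate(classes):
        if not gap_ok:
            breaks[c] = True
    run_start = None
    for c in range(n + 1):
        noncons = c < n and not classes[c][1]
        if noncons and run_start is None:
            run_start = c
        elif not noncons and run_start is not None:
            if c - run_start > p.max_noncons_run:
                for k in range(run_start, c):
                    breaks[k] = True
            run_start = None

    blocks: list[tuple[int, int]] = []
    c = 0
    while c < n:
        if breaks[c]:
            c += 1
            continue
        start = c
        while c < n and not breaks[c]:
            c += 1
        end = c
        # trim flanks to strict columns
        while start < end and not classes[start][2]:
            start += 1
        while end > start and not classes[end - 1][2]:
            end -= 1
        if end - start >= p.min_block_len:
            blocks.append((start, end))

    if not blocks:
        logger.warning("no conserved block survived trimming")
        trimmed = MultipleAlignment(list(msa.names), ["" for _ in msa.rows])
        return BlockTrimming([], p), trimmed

    rows = [
        "".join(r[a:b] for a, b in blocks) for r in msa.rows
    ]
    return BlockTrimming(blocks, p), MultipleAlignment(list(msa.names), rows)


# ---------------------------------------------------------------------------
# Robinson-Foulds


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    tips = sorted(t.name for t in tree.tips())
    all_tips = frozenset(tips)
    ref = tips[0]
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Symmetric-difference (Robinson-Foulds) distance between two trees on
    the same leaves, with normalization by 2(n-3).

    Only resolved (non-trivial) bipartitions are counted, so comparing a
    star tree against anything contributes only the resolved tree's splits.
    """
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    rf = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
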