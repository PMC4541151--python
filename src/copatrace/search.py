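"""Seeded local nucleotide search against a reference database.

A BLASTN-style search: exact-word seeding on both strands, ungapped X-drop
extension, then banded gapped (affine) extension around promising segments.
Hit significance uses Karlin–Altschul statistics, E = m * n * 2**(-bits) with
bits = (lambda * S - ln K) / ln 2, where m is the contig length and n the
total database length.  Screening (alignment length >= 40 bp, E <= 1e-4 by
default) is a separate stage so that raw search output stays inspectable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .refdb import ReferenceDB

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Ungapped K values for supported (match, mismatch) score pairs, reduced by
# gcd; lambda is always solved from the Karlin-Altschul identity.  K is
# invariant under uniform scaling of the scores.
_KAPPA_TABLE: dict[tuple[int, int], float] = {
    (1, -2): 0.621,
    (1, -3): 0.711,
    (1, -4): 0.738,
    (2, -3): 0.775,
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def solve_karlin_altschul(match: int, mismatch: int) -> tuple[float, float]:
    """Solve for (lambda, K) under uniform base frequencies.

    lambda is the unique positive root of
    ``(1/4) e**(lambda*match) + (3/4) e**(lambda*mismatch) = 1``.
    K comes from a fixed lookup of supported score pairs (after dividing both
    scores by their gcd; K is unchanged under uniform scaling).
    """
    if not (match > 0 > mismatch):
        raise ValueError("invalid scoring scheme: require match > 0 > mismatch")
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ValueError(
            "invalid scoring scheme: expected score per aligned pair must be negative"
        )

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    # f(0)=0; the positive root lies below ln(4)/match where the match term
    # alone reaches 1.
    hi = math.log(4.0) / match
    lam = brentq(f, 1e-9, hi, xtol=1e-14, rtol=1e-15)

    g = math.gcd(match, -mismatch)
    key = (match // g, mismatch // g)
    if key not in _KAPPA_TABLE:
        raise ValueError(
            f"no tabulated K for scoring pair {match}/{mismatch}; "
            "supply kappa explicitly via SearchParams"
        )
    return lam, _KAPPA_TABLE[key]


@dataclass
class SearchParams:
    """Scoring and screening parameters for the nucleotide search.

    Defaults mirror legacy blastn: +1/-2 match/mismatch, affine gaps costing
    ``gap_open + L * gap_extend`` for a gap of length L, word size 11.  The
    screening cutoffs (40 bp minimum alignment length, E <= 1e-4) act in
    :func:`filter_hits`, not during the search itself.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float | None = None
    kappa: float | None = None
    max_evalue: float = 1e-4
    min_align_len: int = 40
    min_identity_pct: float = 0.0
    # extension heuristics
    xdrop_ungapped: int = 12
    gapped_trigger: int = 18
    band: int = 32

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.lam is None or self.kappa is None:
            lam, kappa = solve_karlin_altschul(self.match, self.mismatch)
            if self.lam is None:
                self.lam = lam
            if self.kappa is None:
                self.kappa = kappa

    def bit_score(self, raw: int) -> float:
        return (self.lam * raw - math.log(self.kappa)) / math.log(2.0)

    def evalue(self, raw: int, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw))


@dataclass(frozen=True)
class LocalAlignmentHit:
    """One contig-vs-reference local alignment.

    Coordinates are 1-based inclusive on the contig *forward* strand and on
    the reference forward strand; the strand flag records which contig strand
    matched the reference.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    raw_score: int
    bit_score: float
    evalue: float

    def q_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the contig forward strand."""
        return self.q_start - 1, self.q_end


class SeedIndex:
    """Exact-word index over a reference database.

    Maps every word of length ``word_size`` (words containing N are skipped)
    to its (subject record_id, offset) occurrences.
    """

    def __init__(self, db: ReferenceDB, word_size: int) -> None:
        for g in db:
            if len(g) < word_size:
                raise ValueError(
                    f"word_size {word_size} exceeds length of reference {g.record_id}"
                )
        self.word_size = word_size
        self.words: dict[str, list[tuple[str, int]]] = {}
        for g in db:
            seq = g.sequence
            for off in range(len(seq) - word_size + 1):
                w = seq[off : off + word_size]
                if "N" in w:
                    continue
                self.words.setdefault(w, []).append((g.record_id, off))

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.words.values())


def build_word_index(db: ReferenceDB, word_size: int = 11) -> SeedIndex:
    return SeedIndex(db, word_size)


def _ungapped_extend(
    q: str, s: str, qi: int, si: int, w: int, params: SearchParams
) -> tuple[int, int, int, int]:
    """X-drop ungapped extension of an exact seed.

    Returns (q_start, s_start, length, score) of the best-scoring segment
    containing the seed, 0-based on the given orientation of q.
    """
    match, mismatch, xdrop = params.match, params.mismatch, params.xdrop_ungapped
    score = w * match
    best = score
    # extend right
    i, j = qi + w, si + w
    best_right = 0
    cur_right = qi + w
    run = score
    while i < len(q) and j < len(s):
        run += match if q[i] == s[j] else mismatch
        if run > best:
            best = run
            cur_right = i + 1
        if best - run > xdrop:
            break
        i += 1
        j += 1
    best_right = cur_right
    # extend left
    run = best
    best_left = qi
    i, j = qi - 1, si - 1
    while i >= 0 and j >= 0:
        run += match if q[i] == s[j] else mismatch
        if run > best:
            best = run
            best_left = i
        if best - run > xdrop:
            break
        i -= 1
        j -= 1
    length = best_right - best_left
    return best_left, si - (qi - best_left), length, best


def _banded_sw(
    q: str, s: str, dmin: int, dmax: int, params: SearchParams
) -> tuple[int, int, int, int, int, int, int, int] | None:
    """Banded Smith-Waterman with affine gaps, restricted to diagonals
    ``dmin <= i - j <= dmax`` (i indexes q, j indexes s, 0-based).

    Returns (score, q0, q1, s0, s1, matches, mismatches, gap_opens,
    gap_cols) with half-open [q0, q1), [s0, s1), or None when no
    positive-scoring cell exists.
    """
    match, mismatch = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    open_cost = go + ge
    nq, ns = len(q), len(s)
    width = dmax - dmin + 1
    NEG = -(10**9)

    # rows indexed by i (query), columns by j - (i - dmax) in [0, width)
    H_prev = [0] * (width + 2)
    F_prev = [NEG] * (width + 2)
    ptr_H: list[bytearray] = []
    ptr_E: list[bytearray] = []
    ptr_F: list[bytearray] = []

    best = 0
    best_cell = None

    # For row i, valid j range: max(0, i-dmax) .. min(ns-1, i-dmin)
    for i in range(nq):
        jlo = i - dmax
        jhi = i - dmin
        rH = [0] * (width + 2)
        rE = [NEG] * (width + 2)
        rF = [NEG] * (width + 2)
        pH = bytearray(width + 2)
        pE = bytearray(width + 2)
        pF = bytearray(width + 2)
        qi = q[i]
        j0 = max(0, jlo)
        j1 = min(ns - 1, jhi)
        for j in range(j0, j1 + 1):
            c = j - jlo  # column in band arrays, 0..width-1; store at c+1
            k = c + 1
            # E: gap in query (move left in j): from (i, j-1) = same row, k-1
            e_open = rH[k - 1] - open_cost
            e_ext = rE[k - 1] - ge
            if e_open >= e_ext:
                e, pe = e_open, 1
            else:
                e, pe = e_ext, 2
            # F: gap in subject (move up in i): from (i-1, j); in the previous
            # row, jlo was one smaller, so same j sits at column c+1 -> k+1
            f_open = H_prev[k + 1] - open_cost
            f_ext = F_prev[k + 1] - ge
            if f_open >= f_ext:
                f, pf = f_open, 1
            else:
                f, pf = f_ext, 2
            # diagonal from (i-1, j-1): previous row column c -> k
            diag = H_prev[k] + (match if qi == s[j] else mismatch)
            h, ph = 0, 0
            if diag > h:
                h, ph = diag, 1
            if e > h:
                h, ph = e, 2
            if f > h:
                h, ph = f, 3
            rH[k] = h
            rE[k] = e
            rF[k] = f
            pH[k] = ph
            pE[k] = pe
            pF[k] = pf
            if h > best:
                best = h
                best_cell = (i, j)
        ptr_H.append(pH)
        ptr_E.append(pE)
        ptr_F.append(pF)
        H_prev, F_prev = rH, rF

    if best_cell is None or best <= 0:
        return None

    # traceback
    i, j = best_cell
    q1, s1 = i + 1, j + 1
    matches = mismatches = gap_opens = gap_cols = 0
    state = "H"
    while i >= 0 and j >= 0:
        k = (j - (i - dmax)) + 1
        if state == "H":
            ph = ptr_H[i][k]
            if ph == 0:
                break
            if ph == 1:
                if q[i] == s[j]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif ph == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            pe = ptr_E[i][k]
            gap_cols += 1
            if pe == 1:
                gap_opens += 1
                state = "H"
            j -= 1
        else:  # F
            pf = ptr_F[i][k]
            gap_cols += 1
            if pf == 1:
                gap_opens += 1
                state = "H"
            i -= 1
    # the loop stops on the cell *before* the first aligned pair (H source 0
    # or the matrix edge); the alignment starts one step down the diagonal
    q0 = i + 1
    s0 = j + 1
    return best, q0, q1, s0, s1, matches, mismatches, gap_opens, gap_cols


def _segments_for_subject(
    q: str, s: str, seeds: list[tuple[int, int]], params: SearchParams
) -> list[tuple[int, int, int, int]]:
    """Run ungapped extensions over seeds, skipping seeds already covered by
    a previous extension on the same diagonal.  Returns segments as
    (q_start, s_start, length, score), 0-based half-open along q."""
    covered: dict[int, list[tuple[int, int]]] = {}
    segments: list[tuple[int, int, int, int]] = []
    for qi, si in sorted(seeds, key=lambda t: (t[0] - t[1], t[0])):
        d = qi - si
        skip = False
        for a, b in covered.get(d, ()):
            if a <= qi and qi + params.word_size <= b:
                skip = True
                break
        if skip:
            continue
        q0, s0, length, score = _ungapped_extend(q, s, qi, si, params.word_size, params)
        covered.setdefault(d, []).append((q0, q0 + length))
        segments.append((q0, s0, length, score))
    return segments


def _cluster_segments(
    segments: list[tuple[int, int, int, int]], band: int
) -> list[list[tuple[int, int, int, int]]]:
    """Group segments whose diagonals lie within *band* of each other."""
    segs = sorted(segments, key=lambda t: t[0] - t[1])
    clusters: list[list[tuple[int, int, int, int]]] = []
    for seg in segs:
        d = seg[0] - seg[1]
        if clusters and d - (clusters[-1][-1][0] - clusters[-1][-1][1]) <= band:
            clusters[-1].append(seg)
        else:
            clusters.append([seg])
    return clusters


def _hits_overlap(a: LocalAlignmentHit, b: LocalAlignmentHit) -> bool:
    q_olap = min(a.q_end, b.q_end) - max(a.q_start, b.q_start) >= 0
    s_olap = min(a.s_end, b.s_end) - max(a.s_start, b.s_start) >= 0
    return a.strand == b.strand and q_olap and s_olap


def search_contig(
    contig_seq: str,
    contig_id: str,
    index: SeedIndex,
    db: ReferenceDB,
    params: SearchParams | None = None,
) -> list[LocalAlignmentHit]:
    """Search one contig (both strands) against the indexed database.

    Returns all local hits found, including insignificant ones; apply
    :func:`filter_hits` to impose the screening cutoffs.
    """
    params = params or SearchParams()
    contig_seq = contig_seq.upper()
    m = len(contig_seq)
    if m < params.word_size:
        logger.warning(
            "contig %s shorter than word size %d; skipped", contig_id, params.word_size
        )
        return []
    n = db.total_length
    w = params.word_size
    hits: list[LocalAlignmentHit] = []

    for strand in "+-":
        seq = contig_seq if strand == "+" else reverse_complement(contig_seq)
        by_subject: dict[str, list[tuple[int, int]]] = {}
        for i in range(m - w + 1):
            word = seq[i : i + w]
            for subj, off in index.words.get(word, ()):
                by_subject.setdefault(subj, []).append((i, off))
        for subj, seeds in by_subject.items():
            s = db.get(subj).sequence
            segments = _segments_for_subject(seq, s, seeds, params)
            for cluster in _cluster_segments(segments, params.band):
                best_seg = max(cluster, key=lambda t: t[3])
                diags = [t[0] - t[1] for t in cluster]
                if best_seg[3] >= params.gapped_trigger:
                    dmin = min(diags) - params.band
                    dmax = max(diags) + params.band
                    res = _banded_sw(seq, s, dmin, dmax, params)
                    if res is None:
                        continue
                    score, q0, q1, s0, s1, matches, mism, gaps, gap_cols = res
                else:
                    q0, s0, length, score = best_seg
                    q1, s1 = q0 + length, s0 + length
                    matches = sum(
                        1 for a, b in zip(seq[q0:q1], s[s0:s1]) if a == b
                    )
                    mism = length - matches
                    gaps = 0
                    gap_cols = 0
                align_len = matches + mism + gap_cols
                # forward-strand coordinates, 1-based inclusive
                if strand == "+":
                    qs, qe = q0 + 1, q1
                else:
                    qs, qe = m - q1 + 1, m - q0
                hits.append(
                    LocalAlignmentHit(
                        query_id=contig_id,
                        subject_id=subj,
                        identity_pct=100.0 * matches / align_len if align_len else 0.0,
                        align_len=align_len,
                        mismatches=mism,
                        gap_opens=gaps,
                        q_start=qs,
                        q_end=qe,
                        s_start=s0 + 1,
                        s_end=s1,
                        strand=strand,
                        raw_score=score,
                        bit_score=params.bit_score(score),
                        evalue=params.evalue(score, m, n),
                    )
                )

    # merge hits to the same subject that overlap on both query and subject
    merged: list[LocalAlignmentHit] = []
    for hit in sorted(hits, key=lambda h: -h.raw_score):
        if any(
            kept.subject_id == hit.subject_id and _hits_overlap(kept, hit)
            for kept in merged
        ):
            continue
        merged.append(hit)
    merged.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return merged


def search_all(
    contigs: dict[str, str],
    db: ReferenceDB,
    params: SearchParams | None = None,
) -> list[LocalAlignmentHit]:
    """Search every contig in *contigs* (id -> sequence) against *db*."""
    params = params or SearchParams()
    index = build_word_index(db, params.word_size)
    hits: list[LocalAlignmentHit] = []
    for cid, seq in contigs.items():
        hits.extend(search_contig(seq, cid, index, db, params))
    return hits


def filter_hits(
    hits: list[LocalAlignmentHit], params: SearchParams | None = None
) -> list[LocalAlignmentHit]:
    """Apply the screening cutoffs: alignment length, E-value, identity.

    The length threshold is inclusive (a 40 bp alignment passes the default
    40 bp cutoff).  Output is sorted by alignment length descending, then
    E-value ascending, then subject id.
    """
    params = params or SearchParams()
    kept = [
        h
        for h in hits
        if h.align_len >= params.min_align_len
        and h.evalue <= params.max_evalue
        and h.identity_pct >= params.min_identity_pct
    ]
    kept.sort(key=lambda h: (-h.align_len, h.evalue, h.subject_id))
    return kept


def candidate_contigs(hits: list[LocalAlignmentHit]) -> set[str]:
    """Unique contig ids carrying at least one surviving hit."""
    return {h.query_id for h in hits}
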