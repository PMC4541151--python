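"""Full-length gene recovery from candidate contigs.

Contigs carrying screened homology hits are scanned for open reading frames
on all six frames; hits are then assigned to the ORF that contains them, and
the resulting gene models are curated by their identity to the nearest
reference.  ORF scanning is exhaustive and deterministic: every maximal
start-to-stop interval above a length floor is reported, taking the most
upstream start when several starts share a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .refdb import Group, ReferenceDB
from .search import LocalAlignmentHit, reverse_complement

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OpenReadingFrame:
    """An ORF on a contig; coordinates 0-based half-open on the forward strand.

    ``nt_seq`` runs start codon through stop codon inclusive in coding
    orientation; ``aa_seq`` is the translation without the terminal stop,
    with the initiator codon rendered as M (bacterial convention for the
    alternative starts GTG/TTG).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    aa_seq: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RecoveredGene:
    orf: OpenReadingFrame
    best_subject: str
    best_identity_pct: float
    supporting_hits: tuple[LocalAlignmentHit, ...]
    overlap_frac: float
    group: Group = Group.UNKNOWN

    @property
    def gene_id(self) -> str:
        return f"{self.orf.contig_id}|{self.orf.start}-{self.orf.end}({self.orf.strand})"


def _translate_orf(nt: str) -> str:
    aa = str(Seq(nt[:-3]).translate(table=11))
    return ("M" + aa[1:]) if aa else aa


def _scan_strand(
    seq: str,
    contig_id: str,
    strand: str,
    contig_len: int,
    min_len_nt: int,
    start_codons: frozenset[str],
) -> list[OpenReadingFrame]:
    """Scan one orientation of the contig; *seq* is already in coding
    orientation (reverse-complemented for the minus strand)."""
    orfs: list[OpenReadingFrame] = []
    n = len(seq)
    for frame in range(3):
        pending_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending_start is not None:
                    a, b = pending_start, pos + 3
                    if b - a >= min_len_nt:
                        nt = seq[a:b]
                        if strand == "+":
                            start, end = a, b
                        else:
                            start, end = contig_len - b, contig_len - a
                        orfs.append(
                            OpenReadingFrame(
                                contig_id=contig_id,
                                start=start,
                                end=end,
                                strand=strand,
                                frame=frame,
                                nt_seq=nt,
                                aa_seq=_translate_orf(nt),
                            )
                        )
                    pending_start = None
            elif pending_start is None and codon in start_codons:
                pending_start = pos
        # ORFs without an in-frame stop inside the contig are not reported:
        # "full-length" requires both gene ends.
    return orfs


def find_orfs(
    contig_seq: str,
    contig_id: str = "contig",
    min_len_nt: int = 300,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> list[OpenReadingFrame]:
    """Exhaustive six-frame ORF scan.

    Start and stop codons are matched exactly; codons containing N neither
    start nor stop an ORF (they translate to X).  The length floor includes
    the stop codon.  Returned sorted by (start, end, strand).
    """
    seq = contig_seq.upper()
    orfs = _scan_strand(seq, contig_id, "+", len(seq), min_len_nt, start_codons)
    rc = reverse_complement(seq)
    orfs += _scan_strand(rc, contig_id, "-", len(seq), min_len_nt, start_codons)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def map_hits_to_orfs(
    hits: list[LocalAlignmentHit],
    orfs: list[OpenReadingFrame],
    min_overlap_frac: float = 0.5,
) -> tuple[list[RecoveredGene], list[LocalAlignmentHit]]:
    """Assign each hit to the ORF that best contains it.

    A hit is assigned to the same-strand ORF maximizing the overlap with the
    hit's contig interval, provided the overlap covers at least
    *min_overlap_frac* of the hit.  Hits assigned to one ORF merge into a
    single :class:`RecoveredGene`; hits matching no ORF are returned as
    fragment-only evidence.
    """
    by_orf: dict[int, list[tuple[LocalAlignmentHit, float]]] = {}
    fragments: list[LocalAlignmentHit] = []
    for hit in hits:
        h0, h1 = hit.q_interval()
        hit_len = h1 - h0
        best_i, best_key = None, None
        for i, orf in enumerate(orfs):
            if orf.contig_id != hit.query_id or orf.strand != hit.strand:
                continue
            ov = _interval_overlap(h0, h1, orf.start, orf.end)
            if ov == 0 or ov / hit_len < min_overlap_frac:
                continue
            union = (h1 - h0) + len(orf) - ov
            key = (ov / union, -orf.start)
            if best_key is None or key > best_key:
                best_key, best_i = key, i
        if best_i is None:
            fragments.append(hit)
        else:
            orf = orfs[best_i]
            ov = _interval_overlap(h0, h1, orf.start, orf.end)
            by_orf.setdefault(best_i, []).append((hit, ov / hit_len))

    genes: list[RecoveredGene] = []
    for i, pairs in sorted(by_orf.items()):
        pairs.sort(key=lambda p: (-p[0].identity_pct, p[0].subject_id))
        best_hit, _ = pairs[0]
        best_frac = max(frac for h, frac in pairs if h.subject_id == best_hit.subject_id)
        genes.append(
            RecoveredGene(
                orf=orfs[i],
                best_subject=best_hit.subject_id,
                best_identity_pct=best_hit.identity_pct,
                supporting_hits=tuple(h for h, _ in pairs),
                overlap_frac=best_frac,
            )
        )
    return genes, fragments


def curate_candidates(
    genes: list[RecoveredGene],
    db: ReferenceDB,
    min_identity_pct: float = 70.0,
) -> list[RecoveredGene]:
    """Keep genes whose best-reference identity meets the curation cutoff and
    annotate each survivor with its nearest reference's group label."""
    curated = []
    for g in genes:
        if g.best_identity_pct < min_identity_pct:
            continue
        group = db.get(g.best_subject).group if g.best_subject in db else Group.UNKNOWN
        curated.append(replace(g, group=group))
    return curated


def recover_genes(
    contigs: dict[str, str],
    hits: list[LocalAlignmentHit],
    min_orf_nt: int = 300,
    min_overlap_frac: float = 0.5,
) -> tuple[list[RecoveredGene], list[LocalAlignmentHit]]:
    """ORF-call every contig named by *hits* and assign the hits to ORFs."""
    genes: list[RecoveredGene] = []
    fragments: list[LocalAlignmentHit] = []
    by_contig: dict[str, list[LocalAlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.query_id, []).append(h)
    for cid in sorted(by_contig):
        orfs = find_orfs(contigs[cid], cid, min_len_nt=min_orf_nt)
        g, f = map_hits_to_orfs(by_contig[cid], orfs, min_overlap_frac)
        genes.extend(g)
        fragments.extend(f)
    return genes, fragments
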