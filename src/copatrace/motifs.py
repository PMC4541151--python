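"""Conserved-motif screening and family classification of candidate proteins.

The two families that share the *copA* name carry different metal-binding
chemistry: P-type ATPase pumps bind Cu(I) through cysteines -- the CXXC
N-terminal metal-binding motif (HXXH variant), the CPC transmembrane motif
(YPC in an experimentally verified *Sulfolobus solfataricus* pump) -- and
carry the GDGIN ATP-binding motif; multicopper oxidases bind Cu through
histidines in HXH motifs.  A candidate passes the functional screen when the
motifs required for its family are present: for ATPases a transmembrane
metal-binding motif (CPC or YPC) together with GDGIN (CXXC/HXXH are recorded
but optional, since many functional pumps lack them); for multicopper
oxidases at least two distinct HXH sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align_phylo import GAP, MultipleAlignment, global_align_pair
from .recovery import RecoveredGene
from .refdb import Group, ReferenceDB


class MotifCategory(str, Enum):
    METAL_BINDING = "METAL_BINDING"
    ATP_BINDING = "ATP_BINDING"


class FunctionalCall(str, Enum):
    HIGH_POTENTIAL = "HIGH_POTENTIAL"
    INSUFFICIENT_EVIDENCE = "INSUFFICIENT_EVIDENCE"


@dataclass(frozen=True)
class MotifPattern:
    """A motif over the 20 amino acids plus X (pattern X matches any residue;
    a query X never satisfies any pattern position)."""

    name: str
    pattern: str
    group: Group
    category: MotifCategory
    required: bool

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError("motif pattern must be at least 3 residues")


@dataclass(frozen=True)
class MotifMatch:
    pattern_name: str
    start: int  # 1-based on the ungapped protein
    matched_text: str
    in_reference_window: bool = False


@dataclass(frozen=True)
class ScreenResult:
    candidate_id: str
    group_call: Group
    matches: tuple[MotifMatch, ...]
    functional_call: FunctionalCall
    rationale: str


def default_motif_set() -> list[MotifPattern]:
    """The metal- and ATP-binding motifs used for screening."""
    return [
        MotifPattern("CXXC", "CXXC", Group.ATPASE, MotifCategory.METAL_BINDING, False),
        MotifPattern("HXXH", "HXXH", Group.ATPASE, MotifCategory.METAL_BINDING, False),
        MotifPattern("CPC", "CPC", Group.ATPASE, MotifCategory.METAL_BINDING, True),
        MotifPattern("YPC", "YPC", Group.ATPASE, MotifCategory.METAL_BINDING, True),
        MotifPattern("GDGIN", "GDGIN", Group.ATPASE, MotifCategory.ATP_BINDING, True),
        MotifPattern("HXH", "HXH", Group.MCO, MotifCategory.METAL_BINDING, True),
    ]


def scan_motifs(aa: str, patterns: list[MotifPattern]) -> list[MotifMatch]:
    """All (possibly overlapping) pattern occurrences, 1-based positions,
    left to right per pattern."""
    matches: list[MotifMatch] = []
    for pat in patterns:
        plen = len(pat.pattern)
        for i in range(len(aa) - plen + 1):
            window = aa[i : i + plen]
            ok = True
            for p, q in zip(pat.pattern, window):
                if q == "X" or (p != "X" and p != q):
                    ok = False
                    break
            if ok:
                matches.append(MotifMatch(pat.name, i + 1, window))
    return matches


def map_to_reference_alignment(
    candidate_aa: str,
    reference_name: str,
    ref_msa: MultipleAlignment,
) -> dict[int, int | None]:
    """Map candidate residue positions (0-based) to reference-MSA columns.

    The candidate is globally aligned to its nearest reference's ungapped
    row; candidate positions then travel through the reference row's gap
    structure.  Positions falling in candidate-only insertions map to None.
    """
    if reference_name not in ref_msa.names:
        raise KeyError(f"reference {reference_name} is not a row of the alignment")
    ref_row = ref_msa.row(reference_name)
    ref_seq = ref_row.replace(GAP, "")
    _, (cand_al, ref_al) = global_align_pair(candidate_aa, ref_seq)

    # reference position -> MSA column
    ref_pos_to_col: list[int] = [c for c, ch in enumerate(ref_row) if ch != GAP]

    mapping: dict[int, int | None] = {}
    ci = ri = 0
    for a, b in zip(cand_al, ref_al):
        if a != GAP and b != GAP:
            mapping[ci] = ref_pos_to_col[ri]
            ci += 1
            ri += 1
        elif a != GAP:
            mapping[ci] = None
            ci += 1
        else:
            ri += 1
    return mapping


def classify_group(candidate: RecoveredGene, db: ReferenceDB) -> Group:
    """Group label of the candidate's nearest reference (UNKNOWN when the
    reference is unlabeled)."""
    if candidate.best_subject not in db:
        return Group.UNKNOWN
    return db.get(candidate.best_subject).group


@dataclass
class ScreenRules:
    """Boolean rule set deciding HIGH_POTENTIAL calls.

    ATPase: a transmembrane metal-binding motif (CPC or YPC) AND the GDGIN
    ATP-binding motif.  MCO: at least ``mco_min_hxh`` distinct HXH sites.
    UNKNOWN-group candidates never pass.
    """

    atpase_require_tm: bool = True
    atpase_require_atp: bool = True
    mco_min_hxh: int = 2


def functional_screen(
    candidate_aa: str,
    group_call: Group,
    matches: list[MotifMatch],
    rules: ScreenRules | None = None,
    candidate_id: str = "candidate",
) -> ScreenResult:
    """Pure rule application: same inputs always give the same call."""
    rules = rules or ScreenRules()
    by_name: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_name.setdefault(m.pattern_name, []).append(m)

    def positions(name: str) -> list[int]:
        return sorted(m.start for m in by_name.get(name, []))

    notes: list[str] = []
    if group_call == Group.ATPASE:
        tm = positions("CPC") + positions("YPC")
        atp = positions("GDGIN")
        nterm = positions("CXXC") + positions("HXXH")
        ok = True
        if rules.atpase_require_tm:
            notes.append(
                f"transmembrane metal-binding (CPC/YPC): "
                f"{'present at ' + str(sorted(tm)) if tm else 'MISSING'}"
            )
            ok = ok and bool(tm)
        if rules.atpase_require_atp:
            notes.append(
                f"ATP-binding (GDGIN): "
                f"{'present at ' + str(atp) if atp else 'MISSING'}"
            )
            ok = ok and bool(atp)
        notes.append(
            f"N-terminal metal-binding (CXXC/HXXH, optional): "
            f"{'present at ' + str(sorted(nterm)) if nterm else 'absent'}"
        )
        call = FunctionalCall.HIGH_POTENTIAL if ok else FunctionalCall.INSUFFICIENT_EVIDENCE
    elif group_call == Group.MCO:
        hxh = sorted(set(positions("HXH")))
        notes.append(
            f"His metal-binding (HXH) sites: {len(hxh)} at {hxh} "
            f"(need >= {rules.mco_min_hxh})"
        )
        call = (
            FunctionalCall.HIGH_POTENTIAL
            if len(hxh) >= rules.mco_min_hxh
            else FunctionalCall.INSUFFICIENT_EVIDENCE
        )
    else:
        notes.append("group unknown: no rule set applies")
        call = FunctionalCall.INSUFFICIENT_EVIDENCE

    return ScreenResult(
        candidate_id=candidate_id,
        group_call=group_call,
        matches=tuple(matches),
        functional_call=call,
        rationale="; ".join(notes),
    )


def screen_candidates(
    genes: list[RecoveredGene],
    db: ReferenceDB,
    patterns: list[MotifPattern] | None = None,
    rules: ScreenRules | None = None,
) -> list[ScreenResult]:
    """Scan, classify and screen a set of recovered genes."""
    patterns = patterns or default_motif_set()
    results = []
    for g in genes:
        group = classify_group(g, db)
        matches = scan_motifs(g.orf.aa_seq, patterns)
        results.append(
            functional_screen(
                g.orf.aa_seq, group, matches, rules, candidate_id=g.gene_id
            )
        )
    return results
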