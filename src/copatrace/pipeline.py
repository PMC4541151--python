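"""End-to-end pipeline: database validation, search, screening filters, ORF
recovery, curation, motif screening, and optional reference-set phylogeny
with evolutionary-trace motif windows.

Stages communicate only through on-disk artifacts in the output directory so
any stage can be rerun in isolation; a JSON run report records the funnel of
counts (hits >= filtered hits; recovered >= curated >= high-potential).
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import formats
from .align_phylo import nj_tree, progressive_msa, read_newick, robinson_foulds, \
    trim_conserved_blocks, write_msa, write_newick
from .motifs import FunctionalCall, ScreenRules, default_motif_set, screen_candidates
from .recovery import curate_candidates, recover_genes
from .refdb import Group, parse_reference_fasta
from .search import SearchParams, candidate_contigs, filter_hits, search_all
from .trace import motif_columns, partition_tree, trace_ranks

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    contigs: str
    db: str
    out_dir: str
    ref_proteins: str | None = None  # FASTA of reference proteins for ET
    second_tree: str | None = None  # newick for congruence comparison
    group_labels: str | None = None  # TSV record_id -> group
    search: SearchParams = field(default_factory=SearchParams)
    min_orf_nt: int = 300
    min_overlap_frac: float = 0.5
    curation_min_identity_pct: float = 70.0
    et_rank_cutoff: int = 3
    rules: ScreenRules = field(default_factory=ScreenRules)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        search = SearchParams(**raw.pop("search", {}))
        rules = ScreenRules(**raw.pop("rules", {}))
        return cls(search=search, rules=rules, **raw)


@dataclass
class RunReport:
    params: dict
    counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = "copatrace 0.1.0"

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "params": self.params,
            "counts": self.counts,
            "stage_seconds": self.stage_seconds,
            "outputs": self.outputs,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage sequentially, writing intermediates to ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        params={
            "word_size": cfg.search.word_size,
            "min_align_len": cfg.search.min_align_len,
            "max_evalue": cfg.search.max_evalue,
            "min_orf_nt": cfg.min_orf_nt,
            "curation_min_identity_pct": cfg.curation_min_identity_pct,
            "et_rank_cutoff": cfg.et_rank_cutoff,
            "seed": cfg.seed,
        }
    )

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("[%s] start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                report.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("[%s] failed: %s", name, exc)
                    (out / "report.json").write_text(
                        json.dumps(report.as_dict(), indent=2)
                    )
                    raise StageError(name, exc) from exc
                logger.info("[%s] done in %.2fs", name, report.stage_seconds[name])
                return False

        return _Ctx()

    with stage("build-db"):
        db = parse_reference_fasta(cfg.db)
        if cfg.group_labels:
            from .refdb import assign_groups, load_group_labels

            db = assign_groups(db, load_group_labels(cfg.group_labels))
        contigs = formats.read_fasta(cfg.contigs)
        report.counts["db_genes"] = len(db)
        report.counts["contigs"] = len(contigs)

    with stage("search"):
        hits = search_all(contigs, db, cfg.search)
        formats.write_hits_tsv(hits, out / "hits.tsv")
        report.counts["hits"] = len(hits)

    with stage("filter"):
        kept = filter_hits(hits, cfg.search)
        formats.write_hits_tsv(kept, out / "hits.filtered.tsv")
        cands = candidate_contigs(kept)
        (out / "candidate_contigs.txt").write_text(
            "".join(f"{c}\n" for c in sorted(cands))
        )
        report.counts["filtered_hits"] = len(kept)
        report.counts["candidate_contigs"] = len(cands)

    with stage("recover"):
        genes, fragments = recover_genes(
            contigs, kept, cfg.min_orf_nt, cfg.min_overlap_frac
        )
        formats.write_genes_gff3(genes, out / "recovered.gff3")
        formats.write_fasta(
            {g.gene_id: g.orf.nt_seq for g in genes}, out / "recovered.fna"
        )
        formats.write_fasta(
            {g.gene_id: g.orf.aa_seq for g in genes}, out / "recovered.faa"
        )
        report.counts["recovered_genes"] = len(genes)
        report.counts["fragment_only_hits"] = len(fragments)

    with stage("curate"):
        curated = curate_candidates(genes, db, cfg.curation_min_identity_pct)
        formats.write_genes_gff3(curated, out / "curated.gff3")
        formats.write_fasta(
            {g.gene_id: g.orf.aa_seq for g in curated}, out / "curated.faa"
        )
        report.counts["curated_genes"] = len(curated)

    if cfg.ref_proteins:
        with stage("reference-et"):
            ref_prot = formats.read_fasta(cfg.ref_proteins)
            msa = progressive_msa(ref_prot)
            write_msa(msa, out / "reference.afa")
            trimming, trimmed = trim_conserved_blocks(msa)
            (out / "blocks.tsv").write_text(
                "".join(f"{a}\t{b}\n" for a, b in trimming.blocks)
            )
            if trimmed.n_cols >= 1:
                write_msa(trimmed, out / "reference.trimmed.afa")
            n = len(msa.names)
            D = np.zeros((n, n))
            from .align_phylo import percent_identity

            src = trimmed if trimmed.n_cols else msa
            for i in range(n):
                for j in range(i + 1, n):
                    pid = percent_identity((src.rows[i], src.rows[j]))
                    D[i, j] = D[j, i] = 1.0 - pid / 100.0
            tree = nj_tree(D, msa.names)
            write_newick(tree, out / "reference.nwk")
            trace = trace_ranks(msa, tree)
            with open(out / "trace.tsv", "w") as fh:
                fh.write("column\trank\tclass_specific\n")
                for col in trace.columns:
                    fh.write(f"{col.column}\t{col.rank}\t{col.is_class_specific}\n")
            windows = motif_columns(
                trace, msa, default_motif_set(), rank_cutoff=cfg.et_rank_cutoff
            )
            with open(out / "motif_windows.tsv", "w") as fh:
                fh.write("pattern\tgroup\tcolumns\ttext\n")
                for name, wins in sorted(windows.items()):
                    for w in wins:
                        cols = ",".join(map(str, w.columns))
                        fh.write(f"{name}\t{w.group}\t{cols}\t{w.text}\n")
            report.counts["trace_motif_patterns"] = len(windows)
            if cfg.second_tree:
                other = read_newick(cfg.second_tree)
                rf, norm = robinson_foulds(tree, other)
                report.counts["rf_distance"] = rf
                report.counts["rf_normalized"] = round(norm, 4)

    with stage("screen"):
        results = screen_candidates(curated, db, rules=cfg.rules)
        with open(out / "screen.tsv", "w") as fh:
            fh.write("candidate_id\tgroup\tfunctional_call\tmatches\trationale\n")
            for r in results:
                pats = ",".join(
                    f"{m.pattern_name}@{m.start}" for m in r.matches
                )
                fh.write(
                    f"{r.candidate_id}\t{r.group_call.value}\t"
                    f"{r.functional_call.value}\t{pats}\t{r.rationale}\n"
                )
        high = [
            g
            for g, r in zip(curated, results)
            if r.functional_call == FunctionalCall.HIGH_POTENTIAL
        ]
        formats.write_fasta(
            {g.gene_id: g.orf.aa_seq for g in high}, out / "high_potential.faa"
        )
        report.counts["high_potential_genes"] = len(high)

    assert report.counts["hits"] >= report.counts["filtered_hits"]
    assert (
        report.counts["recovered_genes"]
        >= report.counts["curated_genes"]
        >= report.counts["high_potential_genes"]
    )
    (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return report
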