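"""End-to-end mining pipeline: screen → cluster → grammar → classify.

``run_mine`` reproduces the full funnel — homology screen against a
query, greedy identity clustering of the accepted hits, Markov
clustering of the representative similarity graph with retention of the
seed-containing cluster, motif-grammar filtering, and subfamily
classification — writing per-stage TSV reports, a final classification
table, per-proteome putative-sequence counts, and a run log with a
config hash.  One proteome file is treated as one species or strain.

``run_classify`` applies only the grammar + classification stages to a
pre-selected candidate set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from upomine import classify as _classify
from upomine.cluster import (
    SimilarityGraph,
    greedy_identity_cluster,
    mcl_cluster,
    retain_seed_cluster,
)
from upomine.grammar import GrammarResult, aromatic_context, find_core_grammar
from upomine.homology import ScoringScheme, screen_proteome
from upomine.io_formats import ProteinRecord, read_fasta, write_fasta
from upomine.motifs import (
    CYS_PAIR_RULE,
    MotifHit,
    MotifRegistry,
    load_registry,
    cys_pair_evidence,
    scan_registry,
)
from upomine.phylo import distance_matrix, nj_tree, write_newick

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, resolvable defaults < config file < CLI flags."""

    report_evalue: float = 10.0
    accept_evalue: float = 0.01
    identity_threshold: float = 0.90
    word_length: int = 5
    inflation: float = 1.4
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    mcl_prune: float = 1e-8
    group_threshold_kda: float = 35.0
    min_score: float = 0.5
    min_motifs: int = 2
    require_silg: bool = True
    require_sxxrxd: bool = True
    min_length: int = 60
    registry_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold outside (0, 1]")
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.accept_evalue > self.report_evalue:
            raise ValueError("inclusion threshold looser than reporting threshold")

    @classmethod
    def resolve(cls, config_file: str | Path | None = None, **overrides):
        """defaults < YAML config file < explicit keyword overrides."""
        values: dict = {}
        if config_file is not None:
            with open(config_file) as fh:
                values.update(yaml.safe_load(fh) or {})
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def registry(self) -> MotifRegistry:
        return load_registry(self.registry_path)


def _classify_record(
    rec: ProteinRecord,
    grammar: GrammarResult,
    registry: MotifRegistry,
    config: PipelineConfig,
):
    hits: list[MotifHit] = []
    for hlist in scan_registry(registry, rec).values():
        hits.extend(hlist)
    pcp_start = grammar.proximal_cys - 1 if grammar.proximal_cys else None
    if CYS_PAIR_RULE in registry and cys_pair_evidence(rec, pcp_start):
        hits.append(MotifHit(CYS_PAIR_RULE, 0, 0, ""))
    mass = _classify.molecular_weight(rec, config.group_threshold_kda)
    call = _classify.classify_subfamily(
        grammar,
        hits,
        registry,
        record_id=rec.id,
        group=_classify.assign_group(mass),
        min_score=config.min_score,
        min_motifs=config.min_motifs,
    )
    return call, mass, hits


def _grammar(rec: ProteinRecord, registry, config: PipelineConfig) -> GrammarResult:
    return find_core_grammar(
        rec,
        registry,
        require_silg=config.require_silg,
        require_sxxrxd=config.require_sxxrxd,
        min_length=config.min_length,
    )


def _write_classification(calls, masses, aromatics, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "record_id\tgrammar_class\tfamily\tgroup\tweight_kda\tscore\t"
            "aromatics_near_distal\tevidence\tflags\n"
        )
        for call in calls:
            mass = masses[call.record_id]
            fh.write(
                f"{call.record_id}\t{call.grammar_class}\t{call.family}\t"
                f"{call.group}\t{mass.weight_kda:.2f}\t{call.score:.3f}\t"
                f"{aromatics[call.record_id]}\t"
                f"{','.join(call.evidence)}\t{','.join(call.flags)}\n"
            )


def run_classify(
    records: list[ProteinRecord],
    config: PipelineConfig | None = None,
    anchors: dict | None = None,
    anchor_records: list[ProteinRecord] | None = None,
    outdir: str | Path | None = None,
) -> list:
    """Grammar + subfamily calls for a pre-selected candidate set.

    CPO-grammar sequences are placed as Pog / classic CPO when anchor
    sequences with roles are supplied; otherwise they stay flagged
    ``needs-tree``.  Sequences without any grammar are skipped.
    """
    config = config or PipelineConfig()
    registry = config.registry()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    calls = []
    masses = {}
    aromatics = {}
    cpo_calls = []
    kept_records = {}
    for rec in records:
        grammar = _grammar(rec, registry, config)
        if grammar.grammar_class == "none":
            continue
        call, mass, _hits = _classify_record(rec, grammar, registry, config)
        masses[rec.id] = mass
        aromatics[rec.id] = aromatic_context(rec, grammar)
        kept_records[rec.id] = rec
        if "needs-tree" in call.flags:
            cpo_calls.append(call)
        calls.append(call)

    if cpo_calls and anchors and anchor_records:
        taxa = [kept_records[c.record_id] for c in cpo_calls] + list(anchor_records)
        tree = nj_tree(distance_matrix(taxa))
        placed = {
            c.record_id: _classify.place_cpo(c, tree, anchors) for c in cpo_calls
        }
        calls = [placed.get(c.record_id, c) for c in calls]
        if outdir is not None:
            write_newick(tree, Path(outdir) / "placement_tree.nwk")

    if outdir is not None:
        _write_classification(calls, masses, aromatics, outdir / "classification.tsv")
    return calls


def run_mine(
    proteome_paths: list[str | Path],
    query_path: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path = "upomine_run",
    anchors: dict | None = None,
    anchor_records: list[ProteinRecord] | None = None,
    proteomes: list[list[ProteinRecord]] | None = None,
    query: ProteinRecord | None = None,
) -> Path:
    """Execute the full mining funnel and write a run directory.

    Proteomes and query may be given as paths (FASTA) or pre-loaded
    records (``proteomes``/``query``; paths then only label species).
    Returns the run directory.
    """
    config = config or PipelineConfig()
    registry = config.registry()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash\t{config.hash}"]

    if proteomes is None:
        proteomes = [read_fasta(p) for p in proteome_paths]
    if query is None:
        query_records = read_fasta(query_path)
        if not query_records:
            raise ValueError(f"no query sequence in {query_path}")
        query = query_records[0]

    species_of: dict[str, str] = {}
    all_records: list[ProteinRecord] = []
    for path, recs in zip(proteome_paths, proteomes):
        label = Path(str(path)).stem
        for r in recs:
            if r.id in species_of:
                raise ValueError(f"record id {r.id!r} occurs in multiple proteomes")
            species_of[r.id] = label
            all_records.append(r)
    log_lines.append(f"input_sequences\t{len(all_records)}")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # stage 1: homology screen
    scheme = ScoringScheme().with_stats()
    accepted, reported = screen_proteome(
        all_records, query, scheme, config.report_evalue, config.accept_evalue
    )
    by_id = {r.id: r for r in all_records}
    with open(outdir / "screen.tsv", "w") as fh:
        fh.write(
            "query_id\tsubject_id\tpct_identity\talign_len\tq_start\tq_end\t"
            "s_start\ts_end\traw_score\tbit_score\tevalue\taccepted\n"
        )
        accepted_ids = {h.subject_id for h in accepted}
        for h in reported:
            qs = h.query_span or (0, 0)
            ss = h.subject_span or (0, 0)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{qs[1] - qs[0] + 1}\t{qs[0]}\t{qs[1]}\t{ss[0]}\t{ss[1]}\t"
                f"{h.raw_score:.0f}\t{h.bit_score:.1f}\t{h.evalue:.3g}\t"
                f"{int(h.subject_id in accepted_ids)}\n"
            )
    log_lines.append(f"screen_accepted\t{len(accepted)}")
    survivors = [by_id[h.subject_id] for h in accepted]

    # stage 2: greedy identity clustering
    greedy = (
        greedy_identity_cluster(
            survivors, config.identity_threshold, config.word_length, scheme
        )
        if survivors
        else None
    )
    reps = (
        [by_id[r] for r in greedy.representatives] if greedy is not None else []
    )
    if greedy is not None:
        with open(outdir / "greedy_clusters.tsv", "w") as fh:
            fh.write("cluster\tmember\trepresentative\n")
            for k, (cluster, rep) in enumerate(
                zip(greedy.clusters, greedy.representatives)
            ):
                for m in cluster:
                    fh.write(f"{k}\t{m}\t{int(m == rep)}\n")
    log_lines.append(f"greedy_clusters\t{len(reps)}")

    # stage 3: MCL over representatives + seed, retain the seed cluster
    retained_members: list[ProteinRecord] = []
    if reps:
        graph = SimilarityGraph.from_records(reps + [query], scheme)
        mcl = mcl_cluster(
            graph, config.inflation, config.mcl_max_iter, config.mcl_tol,
            config.mcl_prune,
        )
        seed_cluster = retain_seed_cluster(mcl, query.id)
        with open(outdir / "mcl_clusters.tsv", "w") as fh:
            fh.write("cluster\tmember\tseed_cluster\n")
            for k, cluster in enumerate(mcl.clusters):
                for m in cluster:
                    fh.write(f"{k}\t{m}\t{int(m in seed_cluster)}\n")
        for rep_id in seed_cluster:
            if rep_id == query.id:
                continue
            retained_members.extend(by_id[m] for m in greedy.cluster_of(rep_id))
    log_lines.append(f"mcl_retained\t{len(retained_members)}")

    # stages 4-5: grammar filter + classification
    calls = run_classify(
        retained_members, config, anchors, anchor_records, outdir=outdir
    )
    write_fasta(
        [by_id[c.record_id] for c in calls], outdir / "putative_sequences.fasta"
    )
    log_lines.append(f"grammar_passed\t{len(calls)}")

    counts: dict[str, int] = {}
    for c in calls:
        sp = species_of[c.record_id]
        counts[sp] = counts.get(sp, 0) + 1
    with open(outdir / "species_counts.tsv", "w") as fh:
        fh.write("species\tputative_sequences\n")
        for sp in sorted(counts):
            fh.write(f"{sp}\t{counts[sp]}\n")

    with open(outdir / "run_log.tsv", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    logger.info("run complete: %s", "; ".join(log_lines))
    return outdir
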