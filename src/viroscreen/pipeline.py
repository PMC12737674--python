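"""End-to-end orchestration: contigs + hit tables in, per-contig report out.

Stage order: read -> ORFs under the nuclear and mitochondrial tables ->
triage -> end-contamination flags -> coding-system calls (virus candidates
and follow-up contigs) -> motif scan + element classification for
mitochondrially coded contigs -> redundancy clustering of element proteins
-> terminal consensus for declared segment groups -> report.

Steps the source procedure performed manually or against remote services
(HHpred confirmation, NT-database checks, wet-lab validation) are represented
by the ``needs_external_confirmation`` flag, not automated.

The report also carries an ``inferred_class`` per contig, the pipeline's
joint reading of the evidence in the synthetic generator's vocabulary
(H/M/R/G2/P/C/N) so that recovery against planted ground truth is a single
dictionary comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__ as _version
from .cluster import ClusterResult, greedy_cluster
from .coding import CodingSystemCall, classify_coding_system
from .codes import OrfRecord, find_orfs, get_code
from .motifs import (
    DomainAnnotation,
    ElementCall,
    MotifDefinition,
    classify_element,
    default_motifs,
    load_motif_config,
    motif_presence,
    scan_motifs,
)
from .seq import Contig, read_fasta
from .termini import TerminalConsensus, conserved_termini
from .triage import (
    EndFlag,
    HitRecord,
    TriageDecision,
    best_hit_per_query,
    flag_end_contamination,
    read_hit_table,
    triage_contigs,
)

logger = logging.getLogger("viroscreen")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent pipeline input data (CLI exit code 3)."""


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold the pipeline uses, with the procedure's defaults.

    min_orf_aa            minimum ORF length in amino acids (the "-m 100" rule)
    nuclear_table         NCBI translation table for the host nucleus (1)
    mito_table            mold/protozoan mitochondrial table (4)
    host_label            organism label treated as host
    related_host_labels   additional labels treated as host
    identity_threshold    %aa identity below which a non-host best hit is a
                          divergent follow-up (90)
    cluster_min_identity/ redundancy thresholds for collapsing near-identical
    cluster_min_coverage  element proteins (95/95)
    end_window_frac       terminal window, fraction of contig length (0.2)
    host_identity_min     %nt identity for a host end-contamination hit (90)
    """

    min_orf_aa: int = 100
    nuclear_table: int = 1
    mito_table: int = 4
    start_codons: tuple[str, ...] = ("ATG",)
    require_complete: bool = True
    host_label: str = "Botrytis cinerea"
    related_host_labels: tuple[str, ...] = ()
    identity_threshold: float = 90.0
    hit_dialect: str = "outfmt6_ext"
    end_window_frac: float = 0.2
    host_identity_min: float = 90.0
    cluster_min_identity: float = 95.0
    cluster_min_coverage: float = 95.0
    termini_max_mismatch: int = 0
    termini_min_len: int = 3
    termini_max_len: int = 30
    motifs: tuple[MotifDefinition, ...] = field(
        default_factory=lambda: tuple(default_motifs())
    )

    def __post_init__(self) -> None:
        checks = [
            (self.min_orf_aa >= 1, "min_orf_aa must be >= 1"),
            (len(self.start_codons) > 0, "start_codons must be nonempty"),
            (0 <= self.identity_threshold <= 100, "identity_threshold must be in [0, 100]"),
            (0 < self.end_window_frac <= 0.5, "end_window_frac must be in (0, 0.5]"),
            (0 <= self.host_identity_min <= 100, "host_identity_min must be in [0, 100]"),
            (0 <= self.cluster_min_identity <= 100, "cluster_min_identity must be in [0, 100]"),
            (0 <= self.cluster_min_coverage <= 100, "cluster_min_coverage must be in [0, 100]"),
            (self.termini_max_mismatch >= 0, "termini_max_mismatch must be >= 0"),
            (1 <= self.termini_min_len <= self.termini_max_len,
             "need 1 <= termini_min_len <= termini_max_len"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        try:
            get_code(self.nuclear_table)
            get_code(self.mito_table)
        except Exception as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "motifs" in raw:
            try:
                raw["motifs"] = tuple(
                    MotifDefinition(
                        name=str(m["name"]),
                        pattern=str(m["pattern"]),
                        min_score=int(m.get("min_score", 1)),
                    )
                    for m in raw["motifs"]
                )
            except (KeyError, TypeError) as exc:
                raise ConfigError(f"{path}: bad motifs entry: {exc}") from exc
        for key in ("start_codons", "related_host_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["motifs"] = [
            {"name": m.name, "pattern": m.pattern, "min_score": m.min_score}
            for m in self.motifs
        ]
        return d


@dataclass
class ContigRecord:
    """Joined per-contig evidence across all stages."""

    contig_id: str
    length: int
    triage: TriageDecision
    end_flag: EndFlag
    coding_call: CodingSystemCall | None = None
    element_call: ElementCall | None = None
    motif_names: tuple[str, ...] = ()
    cluster_representative: str | None = None
    segment_group: str | None = None
    inferred_class: str = "other"
    needs_external_confirmation: bool = False


@dataclass
class PipelineReport:
    records: list[ContigRecord]
    termini: list[TerminalConsensus]
    clusters: dict[str, ClusterResult]
    config: dict
    version: str

    @property
    def inferred(self) -> dict[str, str]:
        return {r.contig_id: r.inferred_class for r in self.records}

    def summary(self) -> dict:
        counts = lambda vals: dict(sorted(pd.Series(list(vals)).value_counts().items()))
        return {
            "n_contigs": len(self.records),
            "triage": counts(r.triage.category for r in self.records),
            "inferred_class": counts(r.inferred_class for r in self.records),
            "element_class": counts(
                r.element_call.element_class
                for r in self.records
                if r.element_call is not None
            ),
            "clusters": {
                cls: len(res.representatives) for cls, res in sorted(self.clusters.items())
            },
            "n_segment_groups": len(self.termini),
        }

    def to_dict(self) -> dict:
        recs = []
        for r in self.records:
            recs.append(
                {
                    "contig_id": r.contig_id,
                    "length": r.length,
                    "category": r.triage.category,
                    "rationale": list(r.triage.rationale),
                    "end_contamination": r.end_flag.call,
                    "coding_call": None if r.coding_call is None else r.coding_call.call,
                    "single_orf": None if r.coding_call is None else r.coding_call.single_orf,
                    "element_class": None
                    if r.element_call is None
                    else r.element_call.element_class,
                    "motifs": list(r.motif_names),
                    "cluster_representative": r.cluster_representative,
                    "segment_group": r.segment_group,
                    "inferred_class": r.inferred_class,
                    "needs_external_confirmation": r.needs_external_confirmation,
                }
            )
        return {
            "version": self.version,
            "config": self.config,
            "summary": self.summary(),
            "termini": [
                {
                    "virus_id": t.virus_id,
                    "five_prime": t.five_prime,
                    "three_prime": t.three_prime,
                    "n_segments": t.n_segments,
                }
                for t in self.termini
            ],
            "records": recs,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def read_segment_groups(path: str | Path) -> dict[str, tuple[str, ...]]:
    """TSV with columns group_id, contig_id (header optional)."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("", "group_id"):
                continue
            if len(parts) < 2:
                raise DataError(f"{path}: malformed segment-group line {line!r}")
            groups.setdefault(parts[0], []).append(parts[1])
    return {g: tuple(m) for g, m in groups.items()}


FOLLOWUP_CATEGORIES = (
    "followup_no_orf",
    "followup_unannotated_orf",
    "followup_divergent_hit",
)

#: element classes whose proteins are deduplicated, CD-HIT style
CLUSTERED_CLASSES = ("retroplasmid", "group_II_intron", "mitovirus_like")


def _infer_class(rec: ContigRecord) -> str:
    """Map joint evidence onto the generator's class vocabulary."""
    if rec.end_flag.call != "none":
        return "C"
    if rec.segment_group is not None:
        return "P"
    element = rec.element_call.element_class if rec.element_call else None
    if element == "retroplasmid":
        return "R"
    if element == "group_II_intron":
        return "G2"
    if rec.triage.category == "virus_candidate":
        return "M" if element == "mitovirus_like" else "virus_candidate"
    if rec.triage.category == "followup_no_orf":
        return "N"
    if rec.triage.category == "host_like":
        return "H"
    return "other"


def run_pipeline_data(
    contigs: Sequence[Contig],
    protein_hits: Sequence[HitRecord],
    nucleotide_hits: Sequence[HitRecord] = (),
    segment_groups: Mapping[str, Sequence[str]] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Run all stages on in-memory inputs; deterministic for fixed inputs."""
    cfg = config or PipelineConfig()
    if not contigs:
        raise DataError("no contigs")
    by_id = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise DataError("duplicate contig ids in input")
    segment_groups = dict(segment_groups or {})
    for gid, members in segment_groups.items():
        missing = [m for m in members if m not in by_id]
        if missing:
            raise DataError(f"segment group {gid!r} references unknown contigs {missing}")

    logger.info(
        "triage thresholds: min_orf_aa=%d tables=(%d,%d) identity<%g%% host=%r",
        cfg.min_orf_aa, cfg.nuclear_table, cfg.mito_table,
        cfg.identity_threshold, cfg.host_label,
    )

    completeness = ("complete",) if cfg.require_complete else None
    orfs_by_code: dict[int, list[OrfRecord]] = {}
    for table in (cfg.nuclear_table, cfg.mito_table):
        code = get_code(table, cfg.start_codons)
        found: list[OrfRecord] = []
        for c in contigs:
            found.extend(
                find_orfs(c, code, cfg.min_orf_aa, completeness_filter=completeness)
            )
        orfs_by_code[table] = found

    best = best_hit_per_query(protein_hits)
    decisions = triage_contigs(
        contigs,
        orfs_by_code,
        best,
        host_label=cfg.host_label,
        identity_threshold=cfg.identity_threshold,
        related_host_labels=cfg.related_host_labels,
    )
    decision_by_id = {d.contig_id: d for d in decisions}

    nt_by_query: dict[str, list[HitRecord]] = {}
    for h in nucleotide_hits:
        nt_by_query.setdefault(h.query_id, []).append(h)

    group_of = {
        m: gid for gid, members in segment_groups.items() for m in members
    }

    records: list[ContigRecord] = []
    proteins_by_class: dict[str, dict[str, str]] = {c: {} for c in CLUSTERED_CLASSES}
    for contig in contigs:
        decision = decision_by_id[contig.id]
        end_flag = flag_end_contamination(
            contig,
            nt_by_query.get(contig.id, ()),
            host_label=cfg.host_label,
            related_host_labels=cfg.related_host_labels,
            end_window_frac=cfg.end_window_frac,
            host_identity_min=cfg.host_identity_min,
        )
        rec = ContigRecord(
            contig_id=contig.id,
            length=contig.length,
            triage=decision,
            end_flag=end_flag,
            segment_group=group_of.get(contig.id),
            needs_external_confirmation=decision.category
            in ("virus_candidate",) + FOLLOWUP_CATEGORIES,
        )
        if decision.category == "virus_candidate" or decision.category in FOLLOWUP_CATEGORIES:
            cc = classify_coding_system(
                contig,
                min_len_aa=cfg.min_orf_aa,
                nuclear_table=cfg.nuclear_table,
                mito_table=cfg.mito_table,
                require_complete=cfg.require_complete,
                start_codons=cfg.start_codons,
            )
            rec.coding_call = cc
            if cc.call == "mitochondrial_coding":
                mito_orfs = [
                    o for o in orfs_by_code[cfg.mito_table] if o.contig_id == contig.id
                ]
                annotations: list[DomainAnnotation] = []
                for orf in mito_orfs:
                    annotations.extend(
                        scan_motifs(orf.protein, cfg.motifs, protein_id=contig.id)
                    )
                element = classify_element(cc, annotations, cfg.motifs)
                rec.element_call = element
                rec.motif_names = tuple(
                    sorted(motif_presence(annotations, cfg.motifs))
                )
                if element.element_class in proteins_by_class and mito_orfs:
                    longest = max(mito_orfs, key=lambda o: o.length_aa)
                    proteins_by_class[element.element_class][contig.id] = longest.protein
            else:
                rec.element_call = classify_element(cc, [], cfg.motifs)
        records.append(rec)

    clusters: dict[str, ClusterResult] = {}
    rep_of: dict[str, str] = {}
    for cls, prots in proteins_by_class.items():
        if not prots:
            continue
        result = greedy_cluster(
            prots,
            min_identity=cfg.cluster_min_identity,
            min_coverage=cfg.cluster_min_coverage,
        )
        clusters[cls] = result
        rep_of.update(result.membership)
    for rec in records:
        rec.cluster_representative = rep_of.get(rec.contig_id)

    termini: list[TerminalConsensus] = []
    for gid in sorted(segment_groups):
        members = [by_id[m] for m in segment_groups[gid]]
        if len(members) < 2:
            logger.warning("segment group %s has <2 segments; skipped", gid)
            continue
        termini.append(
            conserved_termini(
                members,
                virus_id=gid,
                max_mismatch=cfg.termini_max_mismatch,
                min_len=cfg.termini_min_len,
                max_len=cfg.termini_max_len,
            )
        )

    for rec in records:
        rec.inferred_class = _infer_class(rec)

    return PipelineReport(
        records=records,
        termini=termini,
        clusters=clusters,
        config=cfg.snapshot(),
        version=_version,
    )


def run_pipeline(
    contigs_path: str | Path,
    protein_hits_path: str | Path | None = None,
    nt_hits_path: str | Path | None = None,
    segment_groups_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """File-based entry point; see :func:`run_pipeline_data`."""
    cfg = config or PipelineConfig()
    try:
        contigs = read_fasta(contigs_path)
    except (OSError, ValueError) as exc:
        raise DataError(f"stage read_contigs: {exc}") from exc
    try:
        protein_hits = (
            read_hit_table(protein_hits_path, cfg.hit_dialect)
            if protein_hits_path
            else []
        )
        nt_hits = (
            read_hit_table(nt_hits_path, cfg.hit_dialect) if nt_hits_path else []
        )
    except (OSError, ValueError) as exc:
        raise DataError(f"stage read_hits: {exc}") from exc
    groups = (
        read_segment_groups(segment_groups_path) if segment_groups_path else None
    )
    return run_pipeline_data(contigs, protein_hits, nt_hits, groups, cfg)
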