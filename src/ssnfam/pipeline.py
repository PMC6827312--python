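"""End-to-end orchestration: sequences -> hits -> scan -> subfamilies -> HMM validation.

A single config object carries every threshold of the workflow; the defaults
are the published operating point (delineation at E = 1e-55 on a 1e-5..1e-120
grid, >= 20 members with class-level diversity, metanode merge at 1e-85, 75%
redundancy reduction, assignment ceiling 1e-30 with a 1e10 fold margin).
Identical config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import hmm, network, seqio, subfamily
from .pairwise import HitTable, all_vs_all, parse_blast_tabular, write_blast_tabular
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All tunables of the workflow; defaults are the published operating point."""

    fasta: str = ""
    taxonomy: str = ""
    blast_tabular: str = ""            # optional precomputed hit table
    out_dir: str = "ssnfam_out"
    min_coverage: float = 0.95
    alignment_ceiling: float = 1e-5
    thresholds: tuple[float, ...] = network.DEFAULT_GRID
    delineation_threshold: float = 1e-55
    min_size: int = subfamily.DEFAULT_MIN_SIZE
    diversity_rank: str = subfamily.DEFAULT_DIVERSITY_RANK
    min_distinct: int = subfamily.DEFAULT_MIN_DISTINCT
    overrides: tuple[int, ...] = ()
    merge_threshold: float = network.DEFAULT_MERGE_THRESHOLD
    redundancy_identity: float = 0.75
    hmm_best_ceiling: float = hmm.DEFAULT_BEST_CEILING
    hmm_fold: float = hmm.DEFAULT_FOLD
    pr_cutoffs: tuple[float, ...] = hmm.DEFAULT_PR_CUTOFFS
    n_representatives: int = subfamily.DEFAULT_N_REPRESENTATIVES
    calibration_draws: int = hmm.DEFAULT_CALIBRATION_DRAWS
    seed: int = 0
    threads: int = 1

    def validate(self) -> None:
        checks = [
            0.0 <= self.min_coverage <= 1.0,
            self.alignment_ceiling > 0,
            self.delineation_threshold in self.thresholds,
            self.min_size >= 1,
            self.min_distinct >= 1,
            self.merge_threshold <= self.delineation_threshold,
            0.0 < self.redundancy_identity <= 1.0,
            self.hmm_best_ceiling > 0,
            self.hmm_fold >= 1.0,
            self.n_representatives >= 1,
        ]
        if not all(checks):
            raise PipelineError("pipeline config outside documented ranges")

    @classmethod
    def from_yaml(cls, path: str | Path, **flag_overrides) -> "PipelineConfig":
        """Load a config file; explicit keyword flags override file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in flag_overrides.items() if v is not None})
        for key in ("thresholds", "overrides", "pr_cutoffs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunReport:
    """Parameter echo plus per-stage counts and validation results."""

    config: dict
    n_input: int
    n_fragments: int
    n_kept: int
    n_hits: int
    n_subfamilies: int
    n_classified: int
    n_nonclassified: int
    classified_fraction: float
    components_per_threshold: dict[str, int]
    pr: list[dict]
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[SequenceRecord] | None = None,
    coverage: dict[str, float] | None = None,
    hits: HitTable | None = None,
) -> RunReport:
    """Execute the full workflow and write every interface file.

    Inputs may be passed in memory (records/coverage/hits) or read from the
    paths in the config. Stages: fragment filter -> all-vs-all (or BLAST
    import) -> threshold scan -> delineation at the chosen threshold ->
    S+1 HMM library -> scan/assign -> precision-recall.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def _emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        outputs.append(name)
        return path

    # --- stage: input & fragment filter -------------------------------------
    try:
        if records is None:
            records = seqio.read_fasta(config.fasta)
            if config.taxonomy:
                records = seqio.attach_taxonomy(records, config.taxonomy)
                coverage = seqio.read_coverage(config.taxonomy)
        n_input = len(records)
        if coverage is not None:
            kept, fragments = seqio.filter_fragments(
                records, coverage, min_coverage=config.min_coverage
            )
        else:
            kept, fragments = list(records), []
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    # --- stage: pairwise -----------------------------------------------------
    try:
        if hits is None:
            if config.blast_tabular:
                hits = parse_blast_tabular(config.blast_tabular)
            else:
                hits = all_vs_all(
                    kept, ceiling=config.alignment_ceiling, n_jobs=config.threads
                )
        _emit("hits.outfmt6.tsv", lambda p: write_blast_tabular(hits, p))
    except Exception as exc:
        raise PipelineError(f"pairwise stage: {exc}") from exc

    # --- stage: threshold scan ----------------------------------------------
    try:
        node_ids = [r.id for r in kept]
        scan_result = network.threshold_scan(hits, node_ids, config.thresholds)
        _emit(
            "threshold_scan.tsv",
            lambda p: scan_result.to_table().to_csv(p, sep="\t", index=False),
        )
        graph = network.build_graph(hits, node_ids, config.delineation_threshold)
        _emit("ssn.graphml", lambda p: network.write_graphml(graph, p))
        _emit("ssn_edges.tsv", lambda p: network.write_edge_list(graph, p))
        meta = network.contract_metanodes(graph, config.merge_threshold)
        _emit("ssn_metanodes.graphml", lambda p: network.write_graphml(meta, p))
        partition = scan_result.partition_at(config.delineation_threshold)
        _emit("partition.tsv", lambda p: network.write_partition(partition, p))
    except Exception as exc:
        raise PipelineError(f"network stage: {exc}") from exc

    # --- stage: delineation --------------------------------------------------
    try:
        result = subfamily.delineate(
            partition,
            kept,
            min_size=config.min_size,
            diversity_rank=config.diversity_rank,
            min_distinct=config.min_distinct,
            overrides=config.overrides,
        )
        _emit(
            "subfamilies.tsv",
            lambda p: subfamily.membership_table(result).to_csv(p, sep="\t", index=False),
        )
        _emit(
            "subfamily_summary.tsv",
            lambda p: subfamily.summary_table(result, config.diversity_rank).to_csv(
                p, sep="\t", index=False
            ),
        )
        by_id = {r.id: r for r in kept}
        reps: list[SequenceRecord] = []
        for sf in result.subfamilies:
            ids = subfamily.sample_representatives(
                sf, n=config.n_representatives, seed=config.seed + sf.number
            )
            reps.extend(by_id[i] for i in ids)
        _emit("representatives.fasta", lambda p: seqio.write_fasta(reps, p))
    except Exception as exc:
        raise PipelineError(f"delineation stage: {exc}") from exc

    # --- stage: HMM library & validation --------------------------------------
    try:
        members = {
            f"SF{sf.number}": [by_id[i] for i in sorted(sf.members)]
            for sf in result.subfamilies
        }
        remainder = [by_id[i] for i in sorted(result.nonclassified)]
        library = hmm.build_library(
            members,
            remainder,
            redundancy_identity=config.redundancy_identity,
            calibration_draws=config.calibration_draws,
            seed=config.seed,
        )
        _emit("hmm_library.jsonl", lambda p: library.to_jsonl(p))
        assignments = hmm.scan(
            kept, library, best_ceiling=config.hmm_best_ceiling, fold=config.hmm_fold
        )
        _emit(
            "assignments.tsv",
            lambda p: hmm.assignment_table(assignments).to_csv(
                p, sep="\t", index=False, float_format="%.3e"
            ),
        )
        reference = {r.id: None for r in kept}
        for sf in result.subfamilies:
            for i in sf.members:
                reference[i] = f"SF{sf.number}"
        points = hmm.evaluate_library(assignments, reference, config.pr_cutoffs)
        _emit(
            "precision_recall.tsv",
            lambda p: hmm.pr_table(points).to_csv(p, sep="\t", index=False),
        )
    except Exception as exc:
        raise PipelineError(f"hmm stage: {exc}") from exc

    report = RunReport(
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        n_input=n_input,
        n_fragments=len(fragments),
        n_kept=len(kept),
        n_hits=len(hits),
        n_subfamilies=len(result.subfamilies),
        n_classified=sum(sf.size for sf in result.subfamilies),
        n_nonclassified=len(result.nonclassified),
        classified_fraction=result.classified_fraction,
        components_per_threshold={
            f"{t:.0e}": len(p)
            for t, p in zip(scan_result.thresholds, scan_result.partitions)
        },
        pr=[asdict_pr(p) for p in points],
    )
    report.outputs = outputs + ["report.json"]
    report.to_json(out / "report.json")
    logger.info(
        "pipeline done: %d subfamilies, %.3f classified",
        report.n_subfamilies, report.classified_fraction,
    )
    return report


def asdict_pr(p: hmm.PRPoint) -> dict:
    return {
        "cutoff": p.cutoff, "TP": p.tp, "FP": p.fp, "FN": p.fn,
        "precision": p.precision, "recall": p.recall,
    }
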