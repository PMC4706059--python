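"""Master pipeline: truncate -> map/pair -> filter -> dedup -> report.

Each stage persists its outputs and a stats TSV inside the run directory;
a failed run leaves completed stages reusable via ``resume=True`` (a stage
is skipped when its outputs already exist). The configuration is validated
before any stage runs and echoed verbatim into ``run.log``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import align, filtering, report
from .dedup import dedup as dedup_ditags
from .digest import (DigestMap, digest_sequences, parse_enzyme_spec,
                     read_digest, read_fasta, write_digest)
from .truncate import DEFAULT_MIN_LENGTH, ligation_junction, truncate_fastq

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


@dataclass
class PipelineConfig:
    """Everything one run needs; validated up front."""

    genome_fasta: str
    enzyme: str
    enzyme2: Optional[str] = None
    out_dir: str = "hicprep_run"
    sample: str = "sample"
    aligner: str = "builtin"  # builtin | bowtie | bowtie2 | none
    index_prefix: Optional[str] = None
    prealigned_sam: Optional[tuple[str, str]] = None  # with aligner "none"
    size_min: int = filtering.DEFAULT_MIN_SIZE
    size_max: int = filtering.DEFAULT_MAX_SIZE
    mode: str = filtering.SONICATION
    min_read_length: int = DEFAULT_MIN_LENGTH
    mapq_threshold: int = align.DEFAULT_MAPQ_THRESHOLD
    skip_truncation: bool = False  # double digest without fill-in
    keep_rejects: bool = False
    threads: int = 1
    trim_barcode_nt: int = 0  # trim this many 5' bases before mapping
    plots: bool = False

    def validate(self) -> None:
        parse_enzyme_spec(self.enzyme)
        if self.enzyme2:
            parse_enzyme_spec(self.enzyme2)
        if self.mode not in (filtering.SONICATION,
                             filtering.DOUBLE_DIGEST):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.aligner not in ("builtin", "bowtie", "bowtie2", "none"):
            raise PipelineError(f"unknown aligner {self.aligner!r}")
        if self.aligner in ("bowtie", "bowtie2") and not self.index_prefix:
            raise PipelineError(
                f"aligner {self.aligner} requires index_prefix")
        if self.aligner == "none" and not self.prealigned_sam:
            raise PipelineError(
                "aligner 'none' requires pre-aligned per-mate SAM paths")
        filtering.SizeRange(self.size_min, self.size_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "prealigned_sam" in data and data["prealigned_sam"]:
            data["prealigned_sam"] = tuple(data["prealigned_sam"])
        return cls(**data)


@dataclass
class RunResult:
    run_dir: Path
    summary: report.StageSummary
    html_path: Path
    tsv_path: Path
    unique_pairs: list = field(default_factory=list)


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_pipeline(config: PipelineConfig, r1: str | Path, r2: str | Path,
                 resume: bool = False) -> RunResult:
    """Execute all stages in order on one paired FASTQ sample."""
    config.validate()
    for path in (r1, r2):
        if not Path(path).exists():
            raise PipelineError(f"input FASTQ {path} does not exist")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "run.log", "a") as log:
        log.write("# pipeline configuration\n")
        yaml.safe_dump(dataclasses.asdict(config), log)

    if resume and not any(
            stage for stage, name in report.STAGE_FILES.items()
            if not (run_dir / name).exists()):
        # every stage is already persisted: only the report is re-rendered
        summary = report.summarize(run_dir, config.sample)
        html_path, tsv_path = report.render_report([summary], run_dir,
                                                   plots=config.plots)
        return RunResult(run_dir=run_dir, summary=summary,
                         html_path=html_path, tsv_path=tsv_path)

    enzyme1 = parse_enzyme_spec(config.enzyme)
    enzyme2 = parse_enzyme_spec(config.enzyme2) if config.enzyme2 else None
    sequences = read_fasta(config.genome_fasta)
    genome_lengths = {c: len(s) for c, s in sequences.items()}

    # --- digest -------------------------------------------------------
    digest_path = run_dir / "digest.tsv"
    if resume and digest_path.exists():
        digest_map = read_digest(digest_path)
    else:
        digest_map = digest_sequences(
            sequences, Path(config.genome_fasta).name, enzyme1, enzyme2)
        write_digest(digest_map, digest_path)

    # --- truncate -----------------------------------------------------
    trunc1 = run_dir / "trunc_R1.fastq"
    trunc2 = run_dir / "trunc_R2.fastq"
    trunc_stats_path = run_dir / report.STAGE_FILES["truncate"]
    junction = ligation_junction(enzyme1)
    if resume and _stage_done([trunc1, trunc2, trunc_stats_path]):
        partial = report_read_stage(run_dir, "truncate")
        tstats = partial
    else:
        try:
            if config.skip_truncation:
                import shutil
                shutil.copyfile(r1, trunc1)
                shutil.copyfile(r2, trunc2)
                from .truncate import TruncationStats, read_fastq
                n1 = sum(1 for _ in read_fastq(trunc1))
                n2 = sum(1 for _ in read_fastq(trunc2))
                tstats = {1: TruncationStats(reads_total=n1),
                          2: TruncationStats(reads_total=n2)}
            else:
                s1, s2 = truncate_fastq(r1, r2, junction, trunc1, trunc2,
                                        config.min_read_length)
                tstats = {1: s1, 2: s2}
        except Exception as exc:
            raise PipelineError(
                f"truncation stage failed on {r1}/{r2}: {exc}") from exc

    # --- map + pair ---------------------------------------------------
    try:
        streams = []
        for mate, fq in ((1, trunc1), (2, trunc2)):
            if config.aligner == "builtin":
                results = list(_builtin_results(fq, sequences, mate,
                                                config.trim_barcode_nt))
                align.write_single_end_sam(
                    results, genome_lengths, run_dir / f"mate{mate}.sam")
            elif config.aligner == "none":
                sam = config.prealigned_sam[mate - 1]
                results = list(align.results_from_sam(
                    sam, mate, "bowtie2", config.mapq_threshold))
            else:
                sam = run_dir / f"mate{mate}.sam"
                align.align_external(fq, config.index_prefix, sam,
                                     config.aligner, config.threads)
                results = list(align.results_from_sam(
                    sam, mate, config.aligner, config.mapq_threshold))
            streams.append(results)
        ditags, mstats = align.pair_reads(*streams)
    except Exception as exc:
        raise PipelineError(f"mapping stage failed: {exc}") from exc

    # --- filter -------------------------------------------------------
    size_range = filtering.SizeRange(config.size_min, config.size_max)
    valid, fstats = filtering.filter_ditags(ditags, digest_map, size_range,
                                            config.mode)
    filtering.write_pairs_sam(valid, genome_lengths,
                              run_dir / "valid_pairs.sam")
    if config.keep_rejects:
        rejects = [c for c in filtering.classify_stream(
            ditags, digest_map, size_range, config.mode)
            if c.category is not filtering.Category.VALID]
        filtering.write_pairs_sam(rejects, genome_lengths,
                                  run_dir / "rejects.sam",
                                  tag_category=True)

    # --- dedup --------------------------------------------------------
    unique_pairs, dstats = dedup_ditags(valid)
    filtering.write_pairs_sam(unique_pairs, genome_lengths,
                              run_dir / "unique_pairs.sam")

    # --- report -------------------------------------------------------
    summary = report.StageSummary(sample=config.sample,
                                  truncation=tstats, mapping=mstats,
                                  filtering=fstats, dedup=dstats)
    report.write_stage_stats(run_dir, summary)
    html_path, tsv_path = report.render_report([summary], run_dir,
                                               plots=config.plots)
    return RunResult(run_dir=run_dir, summary=summary,
                     html_path=html_path, tsv_path=tsv_path,
                     unique_pairs=unique_pairs)


def _builtin_results(fq: Path, sequences: dict[str, str], mate: int,
                     trim_nt: int):
    from .truncate import read_fastq
    for read_id, seq, _qual in read_fastq(fq):
        yield align.align_read_exact(read_id, mate, seq[trim_nt:],
                                     sequences)


def report_read_stage(run_dir: Path, stage: str):
    """Load one stage's stats back from its TSV (resume support)."""
    from .report import STAGE_FILES, _read_kv
    from .truncate import TruncationStats
    kv = _read_kv(run_dir / STAGE_FILES[stage])
    if stage != "truncate":
        raise ValueError("only truncation stats are reloaded individually")
    return {mate: TruncationStats(
        reads_total=int(kv[f"reads_total_r{mate}"]),
        reads_truncated=int(kv[f"reads_truncated_r{mate}"]),
        truncated_length_sum=int(kv[f"truncated_length_sum_r{mate}"]),
        too_short=int(kv[f"too_short_r{mate}"])) for mate in (1, 2)}
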