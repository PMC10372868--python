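"""Orchestration of classify -> count -> normalize -> call -> validate.

The pipeline consumes basecalled FASTQ per sample plus alignments
produced by any external long-read aligner (SAM/BAM); alignment itself
is deliberately not performed here.  When ground-truth read-to-gene
assignments are available (simulations), an alignment-free path is
used instead.  Every stage is a pure function of its inputs and the
config, so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    GROUP_NUDC_MINUS,
    GROUP_NUDC_PLUS,
    GROUP_PM_MINUS,
    GROUP_PM_PLUS,
    DesignError,
    Thresholds,
    call_dpcoa_genes,
    canonical_group,
    nudc_validate,
    records_to_frame,
)
from .gene_quant import (
    GeneIndex,
    build_count_table,
    count_from_assignments,
    count_genes,
    load_annotation,
    tpm_normalize,
)
from .tag_classify import TagSpec, classify_fastq, load_tag_sequence

logger = logging.getLogger(__name__)

__all__ = ["SampleConfig", "RunConfig", "PipelineError", "run_pipeline", "load_run_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SampleConfig:
    name: str
    group: str
    reads: Path | None = None  # FASTQ (optional when calls are precomputed)
    bam: Path | None = None  # external alignment
    assignments: Path | None = None  # read_id -> gene_id TSV (truth path)

    def __post_init__(self) -> None:
        self.group = canonical_group(self.group)


@dataclass
class RunConfig:
    """Validated run description (usually loaded from YAML)."""

    samples: list[SampleConfig]
    annotation: Path
    tag: str  # literal sequence or FASTA path
    out_dir: Path
    k: int = 12
    window: int = 50
    trim: bool = False
    mapq_min: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def validate(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise DesignError("sample names must be unique")
        groups = [s.group for s in self.samples]
        for required in (GROUP_PM_PLUS, GROUP_PM_MINUS):
            if groups.count(required) < 2:
                raise DesignError(
                    f"design needs >=2 samples in group {required}; found "
                    f"{groups.count(required)}"
                )
        if not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation not found: {self.annotation}")
        for s in self.samples:
            if s.reads is None and s.assignments is None:
                raise DesignError(f"sample {s.name}: needs reads or assignments")
            if s.reads is not None and s.bam is None and s.assignments is None:
                raise DesignError(
                    f"sample {s.name}: alignments (bam) or truth assignments required "
                    "for counting"
                )
            for p in (s.reads, s.bam, s.assignments):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"sample {s.name}: missing file {p}")

    def config_hash(self) -> str:
        payload = {
            "samples": [
                {
                    "name": s.name,
                    "group": s.group,
                    "reads": str(s.reads),
                    "bam": str(s.bam),
                    "assignments": str(s.assignments),
                }
                for s in self.samples
            ],
            "annotation": str(self.annotation),
            "tag": self.tag,
            "k": self.k,
            "window": self.window,
            "trim": self.trim,
            "mapq_min": self.mapq_min,
            "thresholds": vars(self.thresholds),
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Parse the YAML run description into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent

    def resolve(p):
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    samples = [
        SampleConfig(
            name=s["name"],
            group=s["group"],
            reads=resolve(s.get("reads")),
            bam=resolve(s.get("bam")),
            assignments=resolve(s.get("assignments")),
        )
        for s in raw["samples"]
    ]
    thr = Thresholds(**raw.get("thresholds", {}))
    tag = raw["tag"]
    tag_path = resolve(tag)
    if tag_path is not None and tag_path.exists():
        tag = str(tag_path)
    return RunConfig(
        samples=samples,
        annotation=resolve(raw["annotation"]),
        tag=tag,
        out_dir=resolve(raw.get("out_dir", "dpcoa_run")),
        k=int(raw.get("k", 12)),
        window=int(raw.get("window", 50)),
        trim=bool(raw.get("trim", False)),
        mapq_min=int(raw.get("mapq_min", 0)),
        thresholds=thr,
        seed=int(raw.get("seed", 0)),
    )


@contextmanager
def _stage(name: str) -> Iterator[None]:
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %s: done", name)


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    """Write a TSV atomically: .incomplete until fully written."""
    tmp = path.with_name(path.name + ".incomplete")
    df.to_csv(tmp, sep="\t", index=False, **kwargs)
    tmp.replace(path)


def _read_assignments(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"read_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns read_id, gene_id")
    return dict(zip(df["read_id"], df["gene_id"]))


def aligner_command(reads: str, reference: str, out_bam: str = "aln.bam") -> str:
    """The recommended external long-read aligner invocation."""
    return (
        f"minimap2 -ax map-ont --secondary=no {reference} {reads} "
        f"| samtools sort -o {out_bam} && samtools index {out_bam}"
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return the run summary dict.

    Outputs in ``cfg.out_dir``: per-sample TagCall TSVs and
    tagged/untagged FASTQ, long-format counts+TPM TSV, enrichment
    results TSV, a versioned JSON summary with per-group read totals,
    and a log file.  Any stage failure raises :class:`PipelineError`
    naming the stage; partially written files keep a ``.incomplete``
    suffix.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("dpcoa_tagseq")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    logger.info("dpcoa-tagseq %s, seed %d, config sha256 %s", __version__, cfg.seed, cfg.config_hash())

    with _stage("classify"):
        spec = TagSpec(load_tag_sequence(cfg.tag), k=cfg.k, window=cfg.window)
        calls_by_sample: dict[str, dict[str, bool]] = {}
        for s in cfg.samples:
            if s.reads is None:
                raise ValueError(f"sample {s.name}: no reads to classify")
            table = classify_fastq(
                s.reads, spec, out / s.name, trim=cfg.trim, gzip_output=True
            )
            _write_tsv(table, out / f"{s.name}.calls.tsv")
            calls_by_sample[s.name] = dict(zip(table["read_id"], table["tagged"]))
            logger.info(
                "sample %s: %d reads, %d tagged", s.name, len(table), int(table["tagged"].sum())
            )

    with _stage("count"):
        index = GeneIndex(load_annotation(cfg.annotation))
        results = {}
        for s in cfg.samples:
            calls = calls_by_sample[s.name]
            if s.assignments is not None:
                res = count_from_assignments(
                    _read_assignments(s.assignments), index, calls, s.name
                )
            else:
                res = count_genes(s.bam, index, calls, s.name, mapq_min=cfg.mapq_min)
            results[s.name] = res

    with _stage("normalize"):
        # both tag classes of a run share one TPM scale: the run's
        # total assigned reads, not each class's own column sum
        run_totals = pd.Series(
            {name: res.n_assigned for name, res in results.items()}
        )
        tagged = tpm_normalize(
            build_count_table(results.values(), "tagged"), totals=run_totals
        )
        untagged = tpm_normalize(
            build_count_table(results.values(), "untagged"), totals=run_totals
        )
        counts_long = pd.concat(
            [tagged.to_long("tagged"), untagged.to_long("untagged")], ignore_index=True
        )
        _write_tsv(counts_long, out / "counts.tsv")

    design = {s.name: s.group for s in cfg.samples}

    def tagged_tpm_for(sample_names: list[str]):
        return tpm_normalize(
            build_count_table([results[n] for n in sample_names], "tagged"),
            totals=run_totals[sample_names],
        )

    with _stage("call"):
        pm_samples = [
            s.name for s in cfg.samples if s.group in (GROUP_PM_PLUS, GROUP_PM_MINUS)
        ]
        pm_tagged = tagged_tpm_for(pm_samples)
        records = call_dpcoa_genes(pm_tagged, design, cfg.thresholds)

    with _stage("validate"):
        nudc_minus = [s.name for s in cfg.samples if s.group == GROUP_NUDC_MINUS]
        nudc_plus = [s.name for s in cfg.samples if s.group == GROUP_NUDC_PLUS]
        if nudc_minus and nudc_plus:
            records = nudc_validate(
                records,
                tagged_tpm_for(nudc_minus),
                tagged_tpm_for(nudc_plus),
                cfg.thresholds,
            )
        _write_tsv(records_to_frame(records), out / "results.tsv")

    with _stage("summary"):
        groups: dict[str, dict[str, int]] = {}
        for s in cfg.samples:
            res = results[s.name]
            calls = calls_by_sample[s.name]
            g = groups.setdefault(
                s.group,
                {"reads": 0, "tagged": 0, "untagged": 0, "assigned": 0, "ambiguous": 0, "unassigned": 0},
            )
            g["reads"] += len(calls)
            n_tagged = sum(calls.values())
            g["tagged"] += int(n_tagged)
            g["untagged"] += len(calls) - int(n_tagged)
            g["assigned"] += res.n_assigned
            g["ambiguous"] += res.n_ambiguous
            g["unassigned"] += res.n_unassigned
        summary = {
            "schema_version": 1,
            "software_version": __version__,
            "seed": cfg.seed,
            "config_sha256": cfg.config_hash(),
            "thresholds": vars(cfg.thresholds),
            "groups": groups,
            "n_genes": len(pm_tagged.genes),
            "n_genes_called": sum(r.called for r in records),
            "n_genes_nudc_validated": sum(bool(r.nudc_validated) for r in records),
        }
        tmp = out / "summary.json.incomplete"
        tmp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        tmp.replace(out / "summary.json")
    return summary
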