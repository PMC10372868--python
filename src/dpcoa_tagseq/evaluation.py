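"""Benchmark helpers: run the full method on simulated studies.

These glue the simulator to the classifier/counter/caller without any
file I/O, for power and calibration studies (alignment is bypassed via
the simulator's ground-truth read origins).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .enrichment import EnrichmentRecord, Thresholds, call_dpcoa_genes
from .gene_quant import (
    GeneCountTable,
    GeneIndex,
    build_count_table,
    count_from_assignments,
    tpm_normalize,
)
from .read_sim import ExperimentScene, SimConfig, simulate_experiment
from .tag_classify import FastqRecord, TagSpec, find_tag_match

__all__ = ["classify_calls", "scene_tagged_tpm", "spike_recovery_trial"]


def classify_calls(reads: Iterable[FastqRecord], spec: TagSpec) -> dict[str, bool]:
    """read_id -> tagged? for an in-memory read set."""
    idx = spec.seed_index
    return {
        rec.read_id: find_tag_match(rec.sequence, spec, _seed_index=idx) is not None
        for rec in reads
    }


def scene_tagged_tpm(scene: ExperimentScene) -> GeneCountTable:
    """Classify every sample of a scene and build its tagged TPM table.

    Reads are assigned to genes by their true origin (the scene is
    synthetic, so alignment adds nothing); TPM uses each run's total
    assigned reads as denominator.
    """
    index = GeneIndex(scene.models)
    spec = scene.config.tag
    results = []
    for sample, recs in scene.reads.items():
        calls = classify_calls(recs, spec)
        truth = scene.truth[sample]
        assignments = dict(zip(truth["read_id"], truth["gene_id"]))
        results.append(count_from_assignments(assignments, index, calls, sample))
    totals = pd.Series({r.sample: r.n_assigned for r in results})
    return tpm_normalize(build_count_table(results, "tagged"), totals=totals)


def spike_recovery_trial(
    seed: int,
    *,
    n_genes: int = 50,
    n_capped: int = 5,
    n_reads: int = 5000,
    n_replicates: int = 3,
    thresholds: Thresholds = Thresholds(),
) -> tuple[set[str], set[str], list[EnrichmentRecord]]:
    """One end-to-end spike-in recovery run.

    Simulates a PM+/PM- study, runs classification, counting, TPM and
    calling, and returns (called set, true capped set, records).
    """
    cfg = SimConfig(n_genes=n_genes, n_capped_genes=n_capped, n_reads=n_reads, seed=seed)
    scene = simulate_experiment(cfg, groups=("PM+", "PM-"), n_replicates=n_replicates)
    tagged = scene_tagged_tpm(scene)
    records = call_dpcoa_genes(tagged, scene.design, thresholds)
    called = {r.gene_id for r in records if r.called}
    return called, set(scene.capped_genes), records
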