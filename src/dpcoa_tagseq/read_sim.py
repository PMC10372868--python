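"""Synthetic direct-RNA read and count-table simulator with known truth.

The generator emulates what a cap-tagging direct-RNA run looks like at
the basecall level, so the classifier, counter and caller can be
exercised end to end without real flowcell data:

* a synthetic transcriptome of single-exon genes (uniform base
  composition), each on its own contig, including a 277-nt spike-in
  scale option;
* reads that carry the 40-nt tag barcode at the 5' end with a
  configurable capture probability for capped genes (chemical
  labelling is well below 100% efficient);
* an elevated substitution window of +/- 10 nt around the tag-to-
  transcript junction, mimicking the basecall miscalls caused by the
  non-phosphodiester chemical linkage disrupting the nanopore current;
* global per-base substitution/insertion/deletion errors at
  nanopore-like rates;
* geometric 5'-end truncation (molecules entering the pore late or
  fragmenting) and a 3' poly(A) tail.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_quant import GeneCountTable, GeneModel, tpm_normalize
from .tag_classify import FastqRecord, TagSpec

__all__ = [
    "DEFAULT_TAG_SEQUENCE",
    "SimConfig",
    "CorruptResult",
    "SimCountScene",
    "ExperimentScene",
    "simulate_transcriptome",
    "corrupt",
    "simulate_reads",
    "simulate_count_tables",
    "simulate_nudc_tables",
    "simulate_experiment",
    "write_fasta",
]

# Synthetic stand-in for the 40-nt maleimide tag barcode; the real tag
# sequence is proprietary to the assay.  Any sequence works for the
# classifier - only its k-mer content matters.
DEFAULT_TAG_SEQUENCE = "GGACTTCGGTCTAACGAAGGCATCCGTAAGGCTAGCAATC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.zeros(256, dtype=np.int8)
_LUT[ord("A")] = 0
_LUT[ord("C")] = 1
_LUT[ord("G")] = 2
_LUT[ord("T")] = 3

_QUAL_CHAR = "?"  # constant Phred-30 placeholder quality


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults reflect a plausible tagging run: nanopore-like error
    rates (5% substitution, 3% insertion, 4% deletion), a strongly
    disrupted +/-10 nt junction window (25% substitutions), ~30%
    chemical capture of capped molecules, 20% of reads losing a
    geometric (mean 50 nt) 5' prefix, and 20-80 nt poly(A) tails.
    """

    n_genes: int = 50
    gene_length_range: tuple[int, int] = (300, 1500)
    n_reads: int = 5000
    n_capped_genes: int = 5
    capped_genes: tuple[str, ...] | None = None
    tagged_capture_rate: float = 0.3
    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.04
    junction_noise_halfwidth: int = 10
    junction_sub_rate: float = 0.25
    five_prime_truncation_rate: float = 0.2
    truncation_mean_nt: float = 50.0
    polyA_length_range: tuple[int, int] = (20, 80)
    tag: TagSpec = field(default_factory=lambda: TagSpec(DEFAULT_TAG_SEQUENCE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tagged_capture_rate",
            "sub_rate",
            "ins_rate",
            "del_rate",
            "junction_sub_rate",
            "five_prime_truncation_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gene_length_range", "polyA_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.n_genes < 1 or self.n_reads < 0:
            raise ValueError("n_genes must be >=1 and n_reads >=0")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"gene{i + 1:0{width}d}" for i in range(self.n_genes)]

    def resolved_capped_genes(self) -> tuple[str, ...]:
        ids = self.gene_ids()
        if self.capped_genes is not None:
            missing = set(self.capped_genes) - set(ids)
            if missing:
                raise ValueError(f"capped_genes not in gene universe: {sorted(missing)}")
            return tuple(self.capped_genes)
        return tuple(ids[: min(self.n_capped_genes, self.n_genes)])


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Independent deterministic generator per simulator stage."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_transcriptome(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Draw ``n_genes`` uniform-composition transcripts plus gene models.

    Each synthetic gene sits alone on its own contig as a single
    forward-strand exon covering the transcript, so splicing and
    antisense overlap - orthogonal to everything tested here - never
    arise.  Deterministic under the config seed.
    """
    rng = _rng_for(cfg, 0)
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    transcripts: dict[str, str] = {}
    models: list[GeneModel] = []
    for gid, length in zip(cfg.gene_ids(), lengths):
        transcripts[gid] = _random_seq(rng, int(length))
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=f"contig_{gid}",
                strand="+",
                exons=((0, int(length)),),
                biotype="coding",
            )
        )
    return transcripts, models


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class CorruptResult:
    sequence: str
    n_sub: int
    n_ins: int
    n_del: int


def corrupt(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> CorruptResult:
    """Apply per-base independent substitution/insertion/deletion errors.

    Substitutions replace a base with a uniformly chosen *different*
    base; insertions add a uniform base after a position; deletions
    drop the base.  Expected output length is ``len(seq) * (1 +
    ins_rate - del_rate)``.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    if n == 0:
        return CorruptResult("", 0, 0, 0)
    idx = _LUT[arr]
    u = rng.random((3, n))
    del_mask = u[0] < del_rate
    sub_mask = (u[1] < sub_rate) & ~del_mask
    ins_mask = u[2] < ins_rate
    shift = rng.integers(1, 4, size=n)
    ins_base = rng.integers(0, 4, size=n)
    new_idx = np.where(sub_mask, (idx + shift) % 4, idx)
    # even slots: surviving (possibly substituted) bases; odd: insertions
    lattice = np.full(2 * n, -1, dtype=np.int8)
    lattice[0::2] = np.where(del_mask, -1, new_idx)
    lattice[1::2] = np.where(ins_mask, ins_base, -1)
    kept = lattice[lattice >= 0]
    out = _BASES[kept].tobytes().decode()
    return CorruptResult(out, int(sub_mask.sum()), int(ins_mask.sum()), int(del_mask.sum()))


def _corrupt_junction(
    molecule: str, junction: int, halfwidth: int, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Elevated substitutions in [junction-halfwidth, junction+halfwidth)."""
    lo = max(0, junction - halfwidth)
    hi = min(len(molecule), junction + halfwidth)
    if hi <= lo or rate <= 0:
        return molecule, 0
    res = corrupt(molecule[lo:hi], rate, 0.0, 0.0, rng)
    return molecule[:lo] + res.sequence + molecule[hi:], res.n_sub


def simulate_reads(
    cfg: SimConfig,
    transcripts: Mapping[str, str],
    *,
    capture_rate: float | None = None,
    sample: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Emit reads and a ground-truth table for one sequencing run.

    Per read: a gene is drawn uniformly; if capped, the tag is
    prepended with probability ``capture_rate`` (default
    ``cfg.tagged_capture_rate``); the junction window is corrupted at
    the elevated rate; global errors are applied; a geometric 5'
    truncation may remove a prefix (possibly eating into the tag,
    which produces the "fake untagged" reads seen in real runs); a
    poly(A) tail is appended last.

    Truth columns: read_id, gene_id, tagged_truth (tag chemically
    attached), capped_truth (gene in the capped set), n_sub, n_ins,
    n_del, n_junction_sub, trunc_bases.
    """
    if rng is None:
        rng = _rng_for(cfg, 1)
    rate = cfg.tagged_capture_rate if capture_rate is None else capture_rate
    capped = set(cfg.resolved_capped_genes())
    missing = capped - set(transcripts)
    if missing:
        raise ValueError(f"capped_genes absent from transcriptome: {sorted(missing)}")
    gene_ids = list(transcripts)
    tag = cfg.tag.tag_sequence
    records: list[FastqRecord] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_reads):
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        is_capped = gid in capped
        tagged = bool(is_capped and rng.random() < rate)
        molecule = tag + transcripts[gid] if tagged else transcripts[gid]
        n_junc = 0
        if tagged:
            molecule, n_junc = _corrupt_junction(
                molecule, len(tag), cfg.junction_noise_halfwidth, cfg.junction_sub_rate, rng
            )
        res = corrupt(molecule, cfg.sub_rate, cfg.ins_rate, cfg.del_rate, rng)
        seq = res.sequence
        trunc = 0
        if cfg.five_prime_truncation_rate > 0 and rng.random() < cfg.five_prime_truncation_rate:
            draw = int(rng.geometric(1.0 / cfg.truncation_mean_nt))
            trunc = min(draw, max(0, len(seq) - 50))  # keep >=50 nt of molecule
            seq = seq[trunc:]
        pa_lo, pa_hi = cfg.polyA_length_range
        seq = seq + "A" * int(rng.integers(pa_lo, pa_hi + 1))
        rid = f"{sample}_read{i + 1:06d}"
        records.append(FastqRecord(read_id=rid, sequence=seq, quality=_QUAL_CHAR * len(seq)))
        truth_rows.append(
            {
                "read_id": rid,
                "gene_id": gid,
                "tagged_truth": tagged,
                "capped_truth": is_capped,
                "n_sub": res.n_sub,
                "n_ins": res.n_ins,
                "n_del": res.n_del,
                "n_junction_sub": n_junc,
                "trunc_bases": trunc,
            }
        )
    return records, pd.DataFrame(truth_rows)


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


@dataclass
class SimCountScene:
    """A simulated tagged-count experiment plus calling ground truth."""

    table: GeneCountTable  # TPM-normalized, PM+ and PM- samples
    design: dict[str, str]
    truth_enriched: set[str]


def simulate_count_tables(
    gene_ids: Sequence[str],
    multipliers: Mapping[str, float],
    *,
    baseline_mean: float = 1.0,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    library_size: int = 50_000,
    seed: int = 0,
) -> SimCountScene:
    """Draw tagged PM+/PM- count tables directly (no reads/alignment).

    Per gene and replicate, tagged counts follow a negative binomial
    (var = m + dispersion * m^2); the PM+ mean is the PM- baseline
    mean times the gene's multiplier (1 = null).  TPM uses the
    standard pipeline normalizer with a per-run denominator of
    ``library_size`` total mapped reads — tagged reads are a small
    slice of a run, so the denominator is dominated by the untagged
    background and does not renormalize the tagged signal away.
    Truth = genes with multiplier > 1.
    """
    if n_replicates < 2:
        raise ValueError("need >=2 replicates per group")
    rng = np.random.default_rng(seed)
    samples = [f"PM+_rep{i + 1}" for i in range(n_replicates)] + [
        f"PM-_rep{i + 1}" for i in range(n_replicates)
    ]
    design = {s: ("PM+" if s.startswith("PM+") else "PM-") for s in samples}
    counts = pd.DataFrame(0, index=list(gene_ids), columns=samples, dtype=np.int64)
    for gid in gene_ids:
        mult = float(multipliers.get(gid, 1.0))
        counts.loc[gid, samples[:n_replicates]] = _nb_draw(
            rng, baseline_mean * mult, dispersion, n_replicates
        )
        counts.loc[gid, samples[n_replicates:]] = _nb_draw(
            rng, baseline_mean, dispersion, n_replicates
        )
    totals = np.maximum(counts.sum(axis=0), library_size)
    table = tpm_normalize(GeneCountTable(counts=counts), totals=totals)
    truth = {g for g, m in multipliers.items() if m > 1.0}
    return SimCountScene(table=table, design=design, truth_enriched=truth)


def simulate_nudc_tables(
    gene_ids: Sequence[str],
    capped_genes: Iterable[str],
    *,
    capped_mean: float = 100.0,
    baseline_mean: float = 1.0,
    residual: float = 0.05,
    dispersion: float = 0.1,
    n_replicates: int = 3,
    library_size: int = 50_000,
    seed: int = 0,
) -> tuple[GeneCountTable, GeneCountTable]:
    """Simulate the pyrophosphatase cap-cleavage contrast.

    Without treatment (NudC-) capped genes keep their tagged signal
    (``capped_mean``); with treatment (NudC+) the cap is cleaved and
    the tagged mean drops to ``residual`` times the untreated mean.
    Uncapped genes sit at the baseline in both tables.  TPM shares the
    per-run ``library_size`` denominator (see
    :func:`simulate_count_tables`).
    """
    rng = np.random.default_rng(seed)
    capped = set(capped_genes)
    cols = [f"rep{i + 1}" for i in range(n_replicates)]
    minus = pd.DataFrame(0, index=list(gene_ids), columns=[f"NudC-_{c}" for c in cols], dtype=np.int64)
    plus = pd.DataFrame(0, index=list(gene_ids), columns=[f"NudC+_{c}" for c in cols], dtype=np.int64)
    for gid in gene_ids:
        m_minus = capped_mean if gid in capped else baseline_mean
        m_plus = m_minus * residual if gid in capped else baseline_mean
        minus.loc[gid] = _nb_draw(rng, m_minus, dispersion, n_replicates)
        plus.loc[gid] = _nb_draw(rng, m_plus, dispersion, n_replicates)
    return (
        tpm_normalize(
            GeneCountTable(counts=minus),
            totals=np.maximum(minus.sum(axis=0), library_size),
        ),
        tpm_normalize(
            GeneCountTable(counts=plus),
            totals=np.maximum(plus.sum(axis=0), library_size),
        ),
    )


# capture probability of the tag per experimental group: the reactive
# maleimide tag captures capped molecules; the unreactive azide tag
# leaves only trace spurious tagging; pyrophosphatase treatment
# removes the cap so capture collapses to a residual.
_GROUP_CAPTURE = {
    "PM+": lambda cfg: cfg.tagged_capture_rate,
    "PM-": lambda cfg: 1e-4,
    "NudC-": lambda cfg: cfg.tagged_capture_rate,
    "NudC+": lambda cfg: cfg.tagged_capture_rate * 0.05,
}


@dataclass
class ExperimentScene:
    """A full simulated study: transcriptome plus per-sample runs."""

    config: SimConfig
    transcripts: dict[str, str]
    models: list[GeneModel]
    reads: dict[str, list[FastqRecord]]  # sample -> FASTQ records
    truth: dict[str, pd.DataFrame]  # sample -> truth table
    design: dict[str, str]  # sample -> group

    @property
    def capped_genes(self) -> tuple[str, ...]:
        return self.config.resolved_capped_genes()


def simulate_experiment(
    cfg: SimConfig,
    *,
    groups: Sequence[str] = ("PM+", "PM-"),
    n_replicates: int = 3,
) -> ExperimentScene:
    """Simulate a replicated multi-group tagging study.

    Each sample is an independent run of :func:`simulate_reads` with a
    group-specific capture rate (see ``_GROUP_CAPTURE``).  Sample
    names are ``<group>_rep<i>``.
    """
    transcripts, models = simulate_transcriptome(cfg)
    reads: dict[str, list[FastqRecord]] = {}
    truth: dict[str, pd.DataFrame] = {}
    design: dict[str, str] = {}
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(groups) * n_replicates + 2)[2:]
    i = 0
    for group in groups:
        if group not in _GROUP_CAPTURE:
            raise ValueError(f"unknown group {group!r}")
        rate = _GROUP_CAPTURE[group](cfg)
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_rep{rep}"
            rng = np.random.default_rng(children[i])
            i += 1
            recs, tr = simulate_reads(
                cfg, transcripts, capture_rate=rate, sample=sample, rng=rng
            )
            reads[sample] = recs
            truth[sample] = tr
            design[sample] = group
    return ExperimentScene(
        config=cfg, transcripts=transcripts, models=models, reads=reads, truth=truth, design=design
    )
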