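# Methods

## The problem

Most eukaryotic mRNAs start with an m⁷G cap, but RNA polymerases can
also initiate transcription with noncanonical initiating nucleotides
(NCINs) such as NAD⁺, FAD or 3′-dephospho-coenzyme A (dpCoA), leaving a
noncanonical cap on the 5′ end. dpCoA caps carry a free thiol, which a
tagging assay exploits: a short maleimide-bearing RNA barcode ("tag
RNA", 40 nt) is chemically ligated to the thiol, the sample is
poly(A)-tailed and sequenced by nanopore direct RNA sequencing, and
capped molecules are recognised in the basecalls by the tag at the read
5′ end. Two controls anchor the analysis: an unreactive (azide-only)
tag that cannot ligate (the PM− group, versus the reactive PM+ group),
and pretreatment with the pyrophosphatase NudC, which cleaves
pyrophosphate-bond caps and should abolish tagging (NudC+ versus
NudC−).

This package implements the downstream data analysis: read
classification, per-gene quantification, enrichment calling and NudC
validation, plus a simulator that generates the whole study with known
ground truth.

## Tag classification

A read is **tagged** when any `k` consecutive tag nucleotides (default
k = 12) occur as an exact match wholly inside the first `window` bases
of the read (default 50). Design choices:

* **Exact-match seeds.** The rule is literal: 12 identical consecutive
  bases. Robustness to nanopore basecall errors comes from redundancy
  — a 40-nt tag presents 29 overlapping 12-mers, so isolated errors
  still leave clean seeds. No edit-distance matching is attempted.
* **Seed containment.** The 12-mer must end at or before base 50
  (start ≤ window − k). On a hit the match is extended greedily to the
  right while read and tag agree; the extension may run past the
  window and is what `--trim` removes before alignment.
* **Leftmost seed wins**; at the same read position the smallest tag
  offset is reported. `N` never matches. Reads shorter than `k` are
  untagged by definition; reads shorter than the window are searched
  over their full length.
* **Forward orientation only** by default: direct RNA reads are
  reported 3′→5′ through the pore and basecalled 5′→3′ in transcript
  sense, so the tag appears in forward orientation. A
  `--both-orientations` flag exists for unusual inputs.

The classifier is index-based (hash of tag k-mers) but is required, by
test, to agree read-for-read with an exhaustive search over every
(read position, tag offset) pair.

With a 40-nt tag, k = 12 and window = 50, the chance that a uniform
random read contains a matching seed is ≈ 39 × 29 × 4⁻¹² ≈ 7 × 10⁻⁵,
so false tagging of random sequence is rare (< 10⁻³, verified on 10⁵
random reads).

## Gene quantification

Alignment is delegated to an external long-read aligner (a map-ont
preset emitting SAM/BAM); the package consumes alignments. Each
primary, mapped alignment is assigned to the gene with the **largest
base-pair overlap** between its aligned reference blocks and the
gene's merged exons, requiring strand agreement. Ties between distinct
genes are *ambiguous*, zero overlap is *unassigned*; both are tallied
and excluded from counts rather than fractionally split. MAPQ
filtering is available (default 0). Coordinates are 0-based half-open
internally; GTF/GFF 1-based closed coordinates are converted at parse
time only.

**TPM here is a read proportion**: `tpm[g,s] = counts[g,s] / total[s] ×
10⁶` with **no gene-length division**, because direct RNA sequencing
reads one molecule per read — this deliberately differs from
short-read TPM. By default a table is normalized against its own
column sums (so each TPM column sums to 10⁶). The pipeline, however,
normalizes the tagged and untagged tables of a run against the run's
**total assigned reads**, so both tag classes share one per-run TPM
scale. This matters: tagged reads are dominated by genuinely capped
genes, and normalizing the tagged table by tagged totals alone would
make TPM compositional — removing capped signal (as NudC treatment
does) would silently renormalize the remaining genes and invert the
validation contrast.

The 5′-end profile compares, per gene, the genomic positions of the
5′-most aligned base of tagged versus untagged reads (strand-aware:
`reference_start` on +, `reference_end − 1` on −), summarised by the
two-sample Kolmogorov–Smirnov distance D. D is reported as absent when
either class has fewer than `min_reads` (default 5) reads. A D below
≈ 0.25 is, by our simulations, what identical start-site distributions
with realistic 5′-loss jitter look like; the statistic exists to flag
genuinely shifted 5′ architectures, not as a calibrated test.

## Enrichment calling

A gene is called capped when all three hold (strict inequalities;
boundary values fail):

1. mean tagged TPM in PM+ > `tpm_min` (default 2);
2. fold change `mean(PM+) / max(mean(PM−), pseudocount)` > `fc_min`
   (default 5), pseudocount 0.1 TPM;
3. two-sided two-sample t-test p < `alpha` (default 0.05) between the
   PM+ and PM− replicate TPM values.

The t-test is **Student's pooled** test by default — the procedure
this package reproduces used Student's t — with Welch's
unequal-variance variant available (`test="welch"`). When both groups
have exactly zero variance the t statistic is undefined: equal means
give p = 1; unequal means give the exact two-sided permutation bound
`2 / C(nx+ny, nx)` (0.1 at 3-vs-3), a deliberately conservative choice
because exact within-group ties arise from count discreteness, not
biology. Fewer than two replicates in a group leaves p absent and the
gene uncallable. No multiple-testing correction is applied by default,
mirroring the published raw-cutoff procedure; Benjamini–Hochberg is
available behind a flag.

**NudC validation is an annotation, not a filter**: `nudc_fold = mean
tagged TPM(NudC−) / max(mean tagged TPM(NudC+), pseudocount)`;
a gene validates when the fold exceeds `nudc_fc_min` (default 4). The
primary called set is never modified by validation.

## The simulator

The generator emulates what this assay's runs look like at the
basecall level; its defaults are the study conditions every
statistical test in this repository is run under:

| parameter | default | rationale |
|---|---|---|
| substitution / insertion / deletion | 0.05 / 0.03 / 0.04 per base | nanopore direct-RNA error ballpark |
| junction window | ±10 nt at the tag–transcript boundary | the chemical linkage disrupts the current of the adjacent 10–20 nt |
| junction substitution rate | 0.25 | strong local miscalling |
| tagged capture rate | 0.3 | chemical labelling is far below 100%; gel estimates sit near 30% |
| 5′ truncation | rate 0.2, geometric mean 50 nt | molecules fragment / enter late; can delete the tag, producing "fake untagged" reads |
| poly(A) tail | uniform 20–80 nt | enzymatic tailing |
| genes | 50, single-exon, uniform composition, 300–1500 nt, one contig each | splicing is orthogonal to every rule tested |
| reads per sample | 5,000 | desk-scale stand-in for multi-million-read runs |
| PM− residual tagging | 10⁻⁴ | the unreactive control shows trace noise (~10⁻⁴ in the real groups) |
| NudC+ residual capture | 5% of NudC− | incomplete enzymatic cleavage |

Count-table simulation (for stressing the caller without reads) draws
negative-binomial counts with var = m + φm² (dispersion φ = 0.1), PM+
mean = PM− mean × a per-gene multiplier, and normalizes against a
per-run library of 50,000 total mapped reads, so one baseline count ≈
20 TPM — the same order as the background TPMs real runs report. All
randomness flows from a single config seed through spawned generator
streams; identical configs give byte-identical outputs (gzip members
are written with zeroed mtime for this reason).

What the simulator does **not** model: raw ionic-current signal,
learned (sequence-context) error profiles, splicing, antisense or
overlapping genes, expression heterogeneity between genes, mapping
error. Passing tests therefore demonstrate the correctness and
calibration of the *data analysis* under controlled noise, not
performance on any particular flowcell.

## Numerical and degenerate-input choices

* Samples with zero counted reads: TPM set to 0 with a warning.
* Genes missing from a group's table: treated as all-zero TPM.
* Gene with no exon features: a single exon is synthesized from the
  gene span, with a warning.
* Read ids present in alignments but absent from the TagCall table:
  counted as untagged, warned once.
* Trimming a read whose match spans the whole sequence would leave an
  empty record; the read is left untrimmed with a warning.
* 5′ truncation in the simulator is capped so at least 50 nt of
  molecule survive.
* Pipeline outputs are written to `.incomplete` names and renamed on
  stage success, so an aborted run leaves no ambiguous files.

## Sizes used by the test and benchmark suites

Simulated problem sizes are chosen to be decisive yet desk-scale: the
classifier/oracle equivalence uses 10,000 reads at default error
rates; specificity uses 100,000 random reads; null calibration uses 50
tables of 50 genes (2,500 gene-tests); spike recovery runs 20
independent end-to-end studies (50 genes, 5 capped, 3 replicates per
group, 5,000 reads per sample); NudC validation runs 20 simulated
cleavage experiments. `scripts/acceptance.py` recomputes all of these
from scratch at any seed.

## Known limitations

* Exact-seed classification cannot detect a tag whose every 12-mer is
  disrupted; at substitution rates ≳ 0.3 sensitivity decays (the
  monotonicity suite quantifies this trend).
* Ambiguous reads are dropped, so paralog-dense annotations will
  undercount; no EM reassignment is attempted.
* The caller reproduces the published three-criteria procedure; with
  three replicates and a raw p-cutoff it can admit occasional
  low-count false positives — which is precisely why the NudC
  validation annotation exists and is reported alongside every call.
* Isoform-level quantification, GO enrichment and raw-signal analysis
  are out of scope.
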