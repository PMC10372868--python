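"""Enrichment calling for cap-tagged genes, with pyrophosphatase validation.

A gene is called as carrying the noncanonical (dpCoA) cap when its
tagged-read TPM satisfies three criteria simultaneously, comparing the
reactive-tag group (PM+) against the unreactive-tag control (PM-):

  i.   mean tagged TPM in PM+   > tpm_min   (default 2)
  ii.  PM+/PM- mean fold change > fc_min    (default 5)
  iii. two-sided t-test p-value < alpha     (default 0.05)

All three inequalities are strict; boundary values fail.  Calls are
then annotated (not filtered) with the NudC pyrophosphatase contrast:
NudC cleaves pyrophosphate-bond caps, so a genuinely capped gene loses
its tagged signal under treatment and shows a NudC-/NudC+ fold change
above ``nudc_fc_min`` (default 4).

Fold changes use a small TPM pseudocount in the denominator so that
all-zero control means yield finite, comparable values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_quant import GeneCountTable

__all__ = [
    "Thresholds",
    "EnrichmentRecord",
    "DesignError",
    "welch_t_test",
    "fold_change",
    "call_dpcoa_genes",
    "nudc_validate",
    "records_to_frame",
    "GROUP_PM_PLUS",
    "GROUP_PM_MINUS",
    "GROUP_NUDC_MINUS",
    "GROUP_NUDC_PLUS",
]

GROUP_PM_PLUS = "PM+"
GROUP_PM_MINUS = "PM-"
GROUP_NUDC_MINUS = "NudC-"
GROUP_NUDC_PLUS = "NudC+"

# accept common spellings of the group labels found in design tables
_GROUP_ALIASES = {
    "pm+": GROUP_PM_PLUS, "pmplus": GROUP_PM_PLUS, "pm_plus": GROUP_PM_PLUS,
    "pm-": GROUP_PM_MINUS, "pm–": GROUP_PM_MINUS, "pmminus": GROUP_PM_MINUS,
    "pm_minus": GROUP_PM_MINUS,
    "nudc-": GROUP_NUDC_MINUS, "nudc–": GROUP_NUDC_MINUS,
    "nudc_minus": GROUP_NUDC_MINUS,
    "nudc+": GROUP_NUDC_PLUS, "nudc_plus": GROUP_NUDC_PLUS,
}


class DesignError(ValueError):
    """The sample design table is inconsistent with the data."""


def canonical_group(label: str) -> str:
    key = label.strip().lower().replace(" ", "")
    return _GROUP_ALIASES.get(key, label.strip())


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds.

    tpm_min : minimum mean PM+ tagged TPM (criterion i), default 2.
    fc_min : minimum PM+/PM- fold change (criterion ii), default 5.
    alpha : t-test significance level (criterion iii), default 0.05.
    nudc_fc_min : NudC-/NudC+ fold change for cap validation, default 4.
    pseudocount : TPM floor applied to denominators of fold changes,
        default 0.1.
    """

    tpm_min: float = 2.0
    fc_min: float = 5.0
    alpha: float = 0.05
    nudc_fc_min: float = 4.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tpm_min", "fc_min", "alpha", "nudc_fc_min", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class EnrichmentRecord:
    """Per-gene calling outcome.

    ``called`` is the conjunction of the three pass flags; the NudC
    fields stay ``None`` until :func:`nudc_validate` annotates them.
    """

    gene_id: str
    mean_tpm_pm_plus: float
    mean_tpm_pm_minus: float
    fold_change: float
    p_value: float | None
    pass_tpm: bool
    pass_fc: bool
    pass_p: bool
    called: bool
    nudc_fold: float | None = None
    nudc_validated: bool | None = None

    def __post_init__(self) -> None:
        if self.called != (self.pass_tpm and self.pass_fc and self.pass_p):
            raise ValueError(
                f"gene {self.gene_id}: called must equal pass_tpm & pass_fc & pass_p"
            )


def _degenerate_p(x: np.ndarray, y: np.ndarray) -> float:
    """p-value when both groups have zero variance.

    Equal means: p = 1 (no evidence of a difference).  Unequal means:
    the t statistic is undefined, so fall back to the exact two-sided
    permutation bound for perfect separation, 2 / C(nx+ny, nx) — the
    smallest p any exchangeability-based test can report.  With
    typical 3-vs-3 replication that is 0.1, deliberately conservative:
    exact within-group ties are an artifact of discrete counts, not
    evidence.
    """
    if x.mean() == y.mean():
        return 1.0
    from math import comb

    return min(1.0, 2.0 / comb(x.size + y.size, x.size))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Two-sided Welch (unequal-variance) two-sample t-test p-value.

    Degrees of freedom follow Welch-Satterthwaite.  Zero variance in
    both groups is handled by :func:`_degenerate_p`.  Fewer than 2
    observations in either group returns ``None`` — the gene then
    cannot pass the significance criterion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return None
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return _degenerate_p(x, y)
    return _ttest_p(x, y, equal_var=False)


def student_t_test(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Two-sided pooled-variance (Student) two-sample t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return None
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return _degenerate_p(x, y)
    return _ttest_p(x, y, equal_var=True)


def _ttest_p(x: np.ndarray, y: np.ndarray, *, equal_var: bool) -> float:
    import warnings

    with warnings.catch_warnings():
        # near-identical replicate values trip scipy's moment-precision
        # warning; the exact-tie case is already handled upstream
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def fold_change(mean_plus: float, mean_minus: float, pseudocount: float) -> float:
    """mean_plus / max(mean_minus, pseudocount).

    Monotone increasing in ``mean_plus`` and non-increasing in
    ``mean_minus``; the pseudocount keeps the ratio finite when the
    control mean is zero.
    """
    if mean_plus < 0 or mean_minus < 0:
        raise ValueError("means must be non-negative")
    return mean_plus / max(mean_minus, pseudocount)


def _group_samples(
    design: Mapping[str, str], samples: Iterable[str], group: str
) -> list[str]:
    return [s for s in samples if canonical_group(design.get(s, "")) == group]


def _tpm_frame(table: GeneCountTable) -> pd.DataFrame:
    if table.tpm is None:
        raise ValueError("table has no TPM values; run tpm_normalize first")
    return table.tpm


def call_dpcoa_genes(
    tagged_tpm: GeneCountTable,
    design: Mapping[str, str],
    thr: Thresholds = Thresholds(),
    *,
    test: Literal["student", "welch"] = "student",
    bh_correct: bool = False,
) -> list[EnrichmentRecord]:
    """Apply the three calling criteria to a tagged-TPM table.

    ``design`` maps sample name to group label (PM+/PM-/...).  Records
    are returned for every gene, sorted by descending fold change.
    The significance test is Student's pooled two-sample t by default
    (the procedure this reproduces used Student's t); Welch's
    unequal-variance variant is available via ``test="welch"``.  With
    ``bh_correct`` the significance criterion uses Benjamini-Hochberg
    adjusted p-values (off by default: the published procedure applies
    the raw cutoff).
    """
    tpm = _tpm_frame(tagged_tpm)
    plus = _group_samples(design, tpm.columns, GROUP_PM_PLUS)
    minus = _group_samples(design, tpm.columns, GROUP_PM_MINUS)
    if len(plus) < 2 or len(minus) < 2:
        raise DesignError(
            f"need >=2 samples in each of {GROUP_PM_PLUS} and {GROUP_PM_MINUS}; "
            f"found {len(plus)} and {len(minus)}"
        )
    t_fn = welch_t_test if test == "welch" else student_t_test

    raw_p: list[float | None] = []
    rows: list[dict] = []
    for gene in tpm.index:
        x = tpm.loc[gene, plus].to_numpy(dtype=float)
        y = tpm.loc[gene, minus].to_numpy(dtype=float)
        p = t_fn(x, y)
        raw_p.append(p)
        rows.append(
            {
                "gene_id": gene,
                "mean_plus": float(x.mean()),
                "mean_minus": float(y.mean()),
                "fc": fold_change(float(x.mean()), float(y.mean()), thr.pseudocount),
            }
        )

    if bh_correct:
        effective_p = _benjamini_hochberg(raw_p)
    else:
        effective_p = raw_p

    records = []
    for row, p_raw, p_eff in zip(rows, raw_p, effective_p):
        pass_tpm = row["mean_plus"] > thr.tpm_min
        pass_fc = row["fc"] > thr.fc_min
        pass_p = p_eff is not None and p_eff < thr.alpha
        records.append(
            EnrichmentRecord(
                gene_id=row["gene_id"],
                mean_tpm_pm_plus=row["mean_plus"],
                mean_tpm_pm_minus=row["mean_minus"],
                fold_change=row["fc"],
                p_value=p_raw,
                pass_tpm=pass_tpm,
                pass_fc=pass_fc,
                pass_p=pass_p,
                called=pass_tpm and pass_fc and pass_p,
            )
        )
    records.sort(key=lambda r: -r.fold_change)
    return records


def _benjamini_hochberg(pvalues: Sequence[float | None]) -> list[float | None]:
    """BH-adjusted p-values; None entries pass through."""
    idx = [i for i, p in enumerate(pvalues) if p is not None]
    if not idx:
        return list(pvalues)
    ps = np.array([pvalues[i] for i in idx], dtype=float)
    order = np.argsort(ps)
    m = ps.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, j in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, ps[j] * m / rank)
        adj[j] = running
    out: list[float | None] = list(pvalues)
    for i, a in zip(idx, adj):
        out[i] = float(a)
    return out


def nudc_validate(
    records: Sequence[EnrichmentRecord],
    nudc_minus_tpm: GeneCountTable,
    nudc_plus_tpm: GeneCountTable,
    thr: Thresholds = Thresholds(),
) -> list[EnrichmentRecord]:
    """Annotate records with the NudC-/NudC+ cap-validation fold change.

    ``nudc_fold`` is the mean tagged TPM without treatment over the
    mean with treatment (pseudocount floor in the denominator); a gene
    validates when the fold exceeds ``thr.nudc_fc_min``.  The primary
    ``called`` flag is never modified — validation is an annotation.
    Genes absent from either NudC table keep ``None`` in both fields.
    """
    minus = _tpm_frame(nudc_minus_tpm)
    plus = _tpm_frame(nudc_plus_tpm)
    out = []
    for rec in records:
        g = rec.gene_id
        if g not in minus.index or g not in plus.index:
            out.append(replace(rec, nudc_fold=None, nudc_validated=None))
            continue
        m_minus = float(minus.loc[g].mean())
        m_plus = float(plus.loc[g].mean())
        fold = fold_change(m_minus, m_plus, thr.pseudocount)
        out.append(
            replace(rec, nudc_fold=fold, nudc_validated=fold > thr.nudc_fc_min)
        )
    return out


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten records into the results table written by the pipeline."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_tpm_pm_plus": r.mean_tpm_pm_plus,
                "mean_tpm_pm_minus": r.mean_tpm_pm_minus,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "pass_tpm": r.pass_tpm,
                "pass_fc": r.pass_fc,
                "pass_p": r.pass_p,
                "called": r.called,
                "nudc_fold": r.nudc_fold,
                "nudc_validated": r.nudc_validated,
            }
            for r in records
        ]
    )
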