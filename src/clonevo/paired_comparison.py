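"""Shared/unique partitioning of paired samples, burden and clinical summaries,
TP53-stratified VAF counts, Grubbs outlier detection, and validation arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import DIAGNOSIS, RELAPSE, PairedCase, SampleCall

CODING_SUBSET = ("nonsynonymous", "splice_site")


@dataclass(frozen=True)
class PartitionResult:
    """Variant keys present in both samples or private to one timepoint."""

    shared: frozenset
    unique_diagnosis: frozenset
    unique_relapse: frozenset

    @property
    def n_diagnosis(self) -> int:
        return len(self.shared) + len(self.unique_diagnosis)

    @property
    def n_relapse(self) -> int:
        return len(self.shared) + len(self.unique_relapse)


@dataclass(frozen=True)
class GrubbsResult:
    statistic: float
    critical: float
    alpha: float
    outlier_index: Optional[int]
    p_bound: float

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def partition_shared_unique(case: PairedCase) -> PartitionResult:
    """Partition a patient's variants by presence at diagnosis and/or relapse."""
    d = case.diagnosis.keys()
    r = case.relapse.keys()
    return PartitionResult(
        shared=frozenset(d & r),
        unique_diagnosis=frozenset(d - r),
        unique_relapse=frozenset(r - d),
    )


def _restricted_keys(sample: SampleCall, consequence_subset) -> set:
    if consequence_subset is None:
        return sample.keys()
    allowed = set(consequence_subset)
    return {v.key for v in sample.variants if v.consequence in allowed}


def burden_summary(
    cohort: Sequence[PairedCase],
    consequence_subset: Optional[Sequence[str]] = None,
    excluded_patients: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-patient shared/unique burden counts with per-group means.

    ``consequence_subset`` restricts counting to the given consequence
    classes (e.g. ``("nonsynonymous", "splice_site")`` for coding burden).
    Patients in ``excluded_patients`` (burden outliers) are still listed but
    carry ``excluded=True`` and are left out of the appended group means.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    excluded = set(excluded_patients)
    for case in cohort:
        d = _restricted_keys(case.diagnosis, consequence_subset)
        r = _restricted_keys(case.relapse, consequence_subset)
        shared = d & r
        rows.append({
            "patient_id": case.patient_id,
            "treatment": case.treatment,
            "total_diagnosis": len(d),
            "total_relapse": len(r),
            "shared": len(shared),
            "unique_diagnosis": len(d - shared),
            "unique_relapse": len(r - shared),
            "excluded": case.patient_id in excluded,
        })
    df = pd.DataFrame(rows)
    means = (
        df[~df["excluded"]]
        .groupby("treatment")[
            ["total_diagnosis", "total_relapse", "shared",
             "unique_diagnosis", "unique_relapse"]
        ]
        .mean()
    )
    df.attrs["group_means"] = means
    return df


def classify_tp53_status(sample: SampleCall, require_damaging: bool = True) -> str:
    """``mutant`` iff the sample has a nonsynonymous TP53 variant (optionally
    also requiring the damaging/deleterious prediction), else ``wildtype``."""
    for v in sample.variants:
        if v.gene == "TP53" and v.consequence == "nonsynonymous":
            if not require_damaging or v.damaging_pred is True:
                return "mutant"
    return "wildtype"


def vaf_stratified_counts(
    case: PairedCase, vaf_cutoff: float = 0.4, require_damaging: bool = True
) -> pd.DataFrame:
    """Low-VAF (< cutoff) and high-VAF (>= cutoff) SNV counts per timepoint,
    tagged with the sample's TP53 status."""
    rows = []
    for sample in (case.diagnosis, case.relapse):
        snvs = [v for v in sample.variants if v.is_snv]
        low = sum(1 for v in snvs if v.vaf < vaf_cutoff)
        rows.append({
            "patient_id": case.patient_id,
            "timepoint": sample.timepoint,
            "tp53_status": classify_tp53_status(sample, require_damaging),
            "low_vaf": low,
            "high_vaf": len(snvs) - low,
        })
    return pd.DataFrame(rows)


def grubbs_test(
    values: Sequence[float], alpha: float = 0.05, two_sided: bool = True
) -> GrubbsResult:
    """Grubbs' single-outlier test.

    G = max|x_i - mean| / sd (sample sd).  The critical value is the usual
    t-quantile form: G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))
    with t the upper alpha/(2n) (two-sided) or alpha/n (one-sided) quantile
    of Student's t with n-2 degrees of freedom.  ``p_bound`` is the
    Bonferroni upper bound on the p-value.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs' test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs' test requires nonzero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    tail = alpha / (2 * n) if two_sided else alpha / n
    t_crit = stats.t.ppf(1 - tail, n - 2)
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))
    # invert G back to a t-value for the Bonferroni p bound
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p_bound = 0.0
    else:
        t_of_g = math.sqrt(n * (n - 2) * g * g / denom)
        mult = 2 * n if two_sided else n
        p_bound = min(1.0, mult * stats.t.sf(t_of_g, n - 2))
    return GrubbsResult(
        statistic=float(g), critical=float(g_crit), alpha=alpha,
        outlier_index=idx if g > g_crit else None, p_bound=float(p_bound),
    )


def detect_burden_outliers(
    cohort: Sequence[PairedCase], alpha: float = 0.05
) -> List[str]:
    """Iteratively flag patients whose unique-to-relapse burden is a Grubbs
    outlier (the hypermutator-like high-burden screen)."""
    remaining = [(c.patient_id, len(partition_shared_unique(c).unique_relapse))
                 for c in cohort]
    flagged: List[str] = []
    while len(remaining) >= 3:
        counts = [n for _, n in remaining]
        if len(set(counts)) == 1:
            break
        res = grubbs_test(counts, alpha=alpha)
        if not res.is_outlier:
            break
        flagged.append(remaining[res.outlier_index][0])
        remaining.pop(res.outlier_index)
    return flagged


def validation_summary(
    assays: Iterable[Tuple[str, bool]]
) -> dict:
    """Per-class and pooled validation percentages from (class, validated) assays.

    Percentages are returned both to one decimal and to the nearest whole
    percent.
    """
    per_class: dict = {}
    n_total = 0
    n_valid = 0
    for cls, ok in assays:
        a = per_class.setdefault(cls, [0, 0])
        a[0] += 1
        a[1] += int(bool(ok))
        n_total += 1
        n_valid += int(bool(ok))
    if n_total == 0:
        raise ValueError("no assays provided")
    out = {"classes": {}, "pooled": _pct(n_valid, n_total)}
    for cls, (tot, val) in per_class.items():
        out["classes"][cls] = _pct(val, tot)
    return out


def _pct(num: int, den: int) -> dict:
    pct = 100.0 * num / den
    return {
        "validated": num, "total": den, "percent": pct,
        "percent_1dp": round(pct, 1), "percent_whole": int(round(pct)),
    }


def fraction_selected(selected: int, total: int) -> dict:
    """Fraction of variants chosen for orthogonal validation, as a percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    if selected < 0:
        raise ValueError("selected must be nonnegative")
    return _pct(selected, total)


def clinical_summary(cohort: Sequence[PairedCase]) -> dict:
    """Treated/untreated counts and per-group medians of time-to-recurrence
    and survival.  Even-sized groups use the midpoint median; empty groups
    yield missing values."""
    out: dict = {}
    for group in ("treated", "untreated"):
        cases = [c for c in cohort if c.treatment == group]
        ttr = [c.time_to_recurrence_months for c in cases
               if c.time_to_recurrence_months is not None]
        surv = [c.survival_months for c in cases if c.survival_months is not None]
        out[group] = {
            "n": len(cases),
            "median_time_to_recurrence_months":
                float(np.median(ttr)) if ttr else None,
            "median_survival_months": float(np.median(surv)) if surv else None,
        }
    return out
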