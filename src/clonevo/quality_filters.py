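"""Variant-retention filter chain and cohort-level artifact exclusion.

The per-variant chain keeps a call iff

* caller p-value < ``max_caller_p`` (strict),
* Phred quality >= ``min_qual``,
* depth > ``min_depth`` (strict),
* alternate reads >= ``min_alt_reads``,
* VAF >= ``min_vaf``,
* population MAF missing or <= ``max_pop_maf`` (only variants with a
  *recorded* MAF above the cutoff are treated as known common polymorphisms).

The cohort-level step removes a variant key everywhere when the fraction of
distinct *patients* carrying it (at either timepoint) exceeds
``max_patient_fraction`` — such ubiquitous calls are far more likely to be
platform artifacts than recurrent somatic events.  Removal reports attribute
each dropped variant to the first failing rule, in the order above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, List, Optional, Set, Tuple

from .variant_model import SampleCall

log = logging.getLogger(__name__)

RULE_ORDER = ("caller_p", "qual", "depth", "alt_reads", "vaf", "pop_maf")


@dataclass(frozen=True)
class FilterConfig:
    max_caller_p: float = 0.05
    min_qual: float = 20.0
    min_depth: int = 100          # exclusive: depth must be > min_depth
    min_alt_reads: int = 50       # inclusive
    min_vaf: float = 0.08         # inclusive
    max_pop_maf: float = 0.05     # exclusive-above: MAF > cutoff removed
    max_patient_fraction: float = 0.50  # exclusive-above

    @classmethod
    def most_permissive(cls) -> "FilterConfig":
        return cls(max_caller_p=math.inf, min_qual=-math.inf, min_depth=-1,
                   min_alt_reads=0, min_vaf=0.0, max_pop_maf=1.0,
                   max_patient_fraction=1.0)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class FilterReport:
    removed: dict = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})
    kept: int = 0

    @property
    def total(self) -> int:
        return self.kept + sum(self.removed.values())


def _first_failing_rule(v, cfg: FilterConfig) -> Optional[str]:
    for name in ("caller_p", "qual", "depth", "alt_reads", "vaf"):
        if getattr(v, name if name != "qual" else "qual") is None:
            raise ValueError(f"variant {v.key} is missing required field {name!r}")
    if not (v.caller_p < cfg.max_caller_p):
        return "caller_p"
    if not (v.qual >= cfg.min_qual):
        return "qual"
    if not (v.depth > cfg.min_depth):
        return "depth"
    if not (v.alt_reads >= cfg.min_alt_reads):
        return "alt_reads"
    if not (v.vaf >= cfg.min_vaf):
        return "vaf"
    if v.pop_maf is not None and v.pop_maf > cfg.max_pop_maf:
        return "pop_maf"
    return None


def apply_quality_filters(
    sample: SampleCall, cfg: FilterConfig = FilterConfig()
) -> Tuple[SampleCall, FilterReport]:
    """Apply the per-variant retention chain to one sample.

    Returns a new SampleCall with only the kept variants and a FilterReport
    attributing each removal to the first failing rule.
    """
    report = FilterReport()
    kept = []
    for v in sample.variants:
        rule = _first_failing_rule(v, cfg)
        if rule is None:
            kept.append(v)
        else:
            report.removed[rule] += 1
    report.kept = len(kept)
    out = SampleCall(
        patient_id=sample.patient_id, timepoint=sample.timepoint,
        variants=kept, sample_id=sample.sample_id, purity=sample.purity,
        purity_method=sample.purity_method, mgmt_status=sample.mgmt_status,
    )
    return out, report


def exclude_recurrent_artifacts(
    cohort: Iterable[SampleCall], cfg: FilterConfig = FilterConfig()
) -> Tuple[List[SampleCall], Set[tuple]]:
    """Remove variant keys seen in more than ``max_patient_fraction`` of patients.

    Presence in both timepoints of one patient counts once.  Returns the
    rewritten cohort and the set of removed keys.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    patients = {s.patient_id for s in cohort}
    n_patients = len(patients)
    if n_patients < 3:
        log.warning(
            "artifact exclusion on a %d-patient cohort: any shared variant "
            "exceeds the %.0f%% threshold", n_patients,
            100 * cfg.max_patient_fraction,
        )
    carriers: dict = {}
    for s in cohort:
        for key in s.keys():
            carriers.setdefault(key, set()).add(s.patient_id)
    removed = {
        key for key, pats in carriers.items()
        if len(pats) / n_patients > cfg.max_patient_fraction
    }
    out = []
    for s in cohort:
        kept = [v for v in s.variants if v.key not in removed]
        out.append(SampleCall(
            patient_id=s.patient_id, timepoint=s.timepoint, variants=kept,
            sample_id=s.sample_id, purity=s.purity,
            purity_method=s.purity_method, mgmt_status=s.mgmt_status,
        ))
    return out, removed
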