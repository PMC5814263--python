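"""Pyrimidine-collapsed substitution spectra and TMZ-hypermutator calling.

Single-base substitutions are collapsed onto the pyrimidine-containing
strand, giving the six canonical classes C>A, C>G, C>T, T>A, T>C, T>G.  For
the C:G>T:A transition class — the temozolomide (TMZ) alkylation signature —
the dinucleotide context records the base immediately 3' of the mutated
cytosine on the pyrimidine strand (CpA/CpC/CpG/CpT).  TMZ-induced
hypermutation is enriched at CpC and CpT.

A recurrence is called TMZ-hypermutant when, among its relapse-unique SNVs,
the C>T fraction and the CpC/CpT context fraction both clear their
thresholds and (optionally) the patient's relapse-unique burden is a Grubbs
outlier within the cohort.  The numeric thresholds are a conservative
operationalization — the signature literature describes proportions, not a
decision rule — and are fully configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .paired_comparison import grubbs_test, partition_shared_unique
from .variant_model import PairedCase, VariantRecord

log = logging.getLogger(__name__)

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CT_CONTEXTS = ("CpA", "CpC", "CpG", "CpT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SpectrumCounts:
    """Six-class substitution counts plus dinucleotide contexts for C>T."""

    classes: dict = field(default_factory=lambda: {c: 0 for c in SIX_CLASSES})
    ct_contexts: dict = field(default_factory=lambda: {c: 0 for c in CT_CONTEXTS})
    ct_unresolved: int = 0
    n_non_snv: int = 0

    @property
    def total(self) -> int:
        return sum(self.classes.values())

    def ct_fraction(self) -> Optional[float]:
        return self.classes["C>T"] / self.total if self.total else None

    def cpc_cpt_fraction(self) -> Optional[float]:
        resolved = sum(self.ct_contexts.values())
        if resolved == 0:
            return None
        return (self.ct_contexts["CpC"] + self.ct_contexts["CpT"]) / resolved


@dataclass(frozen=True)
class HypermutatorConfig:
    min_ct_fraction: float = 0.60
    min_cpc_cpt_fraction: float = 0.60
    require_burden_outlier: bool = True
    grubbs_alpha: float = 0.05
    min_unique_relapse_snvs: int = 10


@dataclass(frozen=True)
class HypermutatorCall:
    decision: str  # "positive" | "negative" | "insufficient"
    n_unique_relapse_snvs: int
    ct_fraction: Optional[float]
    cpc_cpt_fraction: Optional[float]
    burden_outlier: Optional[bool]


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a single-base substitution onto its pyrimidine representative."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def dinucleotide_context(record: VariantRecord) -> Optional[str]:
    """Dinucleotide context of a C:G>T:A variant, pyrimidine-strand 5'->3'.

    For a reference-C variant the context base is the explicit 3' neighbor;
    for a reference-G (i.e. G>A) variant the 5' neighbor is complemented so
    that the reported dinucleotide is always (mutated C, its 3' neighbor).
    Returns None when the needed context field is missing.
    """
    cls = collapse_substitution(record.ref, record.alt)
    if cls != "C>T":
        raise ValueError(f"dinucleotide context is defined for C>T variants, got {cls}")
    if record.ref == "C":
        base = record.context_3p
    else:  # G>A: pyrimidine strand is the reverse complement
        base = _COMPLEMENT.get(record.context_5p) if record.context_5p else None
    if base not in ("A", "C", "G", "T"):
        return None
    return f"Cp{base}"


def spectrum_counts(variants: Iterable[VariantRecord]) -> SpectrumCounts:
    """Six-class spectrum with C>T dinucleotide-context breakdown.

    Non-SNVs (indels, MNVs) are skipped and counted in ``n_non_snv``.
    """
    out = SpectrumCounts()
    for v in variants:
        if not v.is_snv:
            out.n_non_snv += 1
            continue
        cls = collapse_substitution(v.ref, v.alt)
        out.classes[cls] += 1
        if cls == "C>T":
            ctx = dinucleotide_context(v)
            if ctx is None:
                out.ct_unresolved += 1
            else:
                out.ct_contexts[ctx] += 1
    if out.n_non_snv:
        log.info("spectrum_counts skipped %d non-SNV variants", out.n_non_snv)
    return out


def call_hypermutator(
    case: PairedCase,
    cohort_unique_relapse_counts: Sequence[int],
    cfg: HypermutatorConfig = HypermutatorConfig(),
) -> HypermutatorCall:
    """Decide whether a recurrence shows the TMZ hypermutator signature.

    ``cohort_unique_relapse_counts`` are the relapse-unique variant counts
    of every patient in the cohort (including this one), used for the Grubbs
    burden-outlier requirement.
    """
    part = partition_shared_unique(case)
    relapse_by_key = case.relapse.by_key()
    unique_snvs = [relapse_by_key[k] for k in part.unique_relapse
                   if relapse_by_key[k].is_snv]
    n = len(unique_snvs)
    if n < cfg.min_unique_relapse_snvs:
        return HypermutatorCall("insufficient", n, None, None, None)
    spec = spectrum_counts(unique_snvs)
    ct_frac = spec.ct_fraction()
    ctx_frac = spec.cpc_cpt_fraction()
    outlier: Optional[bool] = None
    ok = (ct_frac is not None and ct_frac >= cfg.min_ct_fraction
          and ctx_frac is not None and ctx_frac >= cfg.min_cpc_cpt_fraction)
    if ok and cfg.require_burden_outlier:
        counts = list(cohort_unique_relapse_counts)
        this = len(part.unique_relapse)
        try:
            res = grubbs_test(counts, alpha=cfg.grubbs_alpha)
            outlier = bool(res.is_outlier and counts[res.outlier_index] == this)
        except ValueError:
            outlier = False
        ok = ok and outlier
    return HypermutatorCall(
        "positive" if ok else "negative", n, ct_frac, ctx_frac, outlier,
    )
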