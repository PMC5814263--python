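"""Domain types and readers/writers for variant, methylation, and cohort tables.

Coordinates are 1-based and fully closed, matching VCF convention.  Variant
identity is the tuple ``(chrom, pos, ref, alt)``; annotations (gene,
consequence, population MAF, sequence context, damaging prediction) are
carried on the record but are never part of identity.

The native variant table is a tab-separated dialect with the header::

    sample_id  patient_id  timepoint  chrom  pos  ref  alt  vaf  depth
    alt_reads  qual  caller_p  gene  consequence  pop_maf  context_5p
    context_3p  damaging_pred

``#``-prefixed comment lines are allowed anywhere; an empty field means
missing.  A standard VCF 4.x reader (per-sample FORMAT keys ``DP``, ``AO``,
``AF``; INFO keys ``GENE``, ``CONSEQ``, ``POPMAF``) is available when
cyvcf2 is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger(__name__)

DIAGNOSIS = "diagnosis"
RELAPSE = "relapse"
TIMEPOINTS = (DIAGNOSIS, RELAPSE)

CONSEQUENCES = ("nonsynonymous", "synonymous", "splice_site", "intronic", "other")

VARIANT_TABLE_COLUMNS = [
    "sample_id", "patient_id", "timepoint", "chrom", "pos", "ref", "alt",
    "vaf", "depth", "alt_reads", "qual", "caller_p", "gene", "consequence",
    "pop_maf", "context_5p", "context_3p", "damaging_pred",
]

COHORT_TABLE_COLUMNS = [
    "patient_id", "gender", "age_at_diagnosis", "primary_diagnosis",
    "recurrence_diagnosis", "treatment_detail", "time_to_recurrence_months",
    "survival_months",
]


class TableFormatError(ValueError):
    """A malformed row or header in one of the text dialects."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample.

    ``vaf`` is the variant allele fraction in [0, 1], ``depth`` the total
    read count at the site and ``alt_reads`` the alternate-supporting read
    count.  ``qual`` is a Phred-scaled quality and ``caller_p`` the variant
    caller's p-value.  Optional annotations default to missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_reads: int
    qual: float
    caller_p: float
    gene: str = ""
    consequence: str = "other"
    pop_maf: Optional[float] = None
    context_5p: Optional[str] = None
    context_3p: Optional[str] = None
    damaging_pred: Optional[bool] = None

    def __post_init__(self):
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf {self.vaf} outside [0, 1] at {self.key}")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} exceeds depth {self.depth} at {self.key}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.key}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and self.ref != "-" and self.alt != "-"

    def with_vaf(self, vaf: float) -> "VariantRecord":
        return replace(self, vaf=float(vaf))


@dataclass
class SampleCall:
    """All retained variants of one specimen (one patient, one timepoint)."""

    patient_id: str
    timepoint: str
    variants: list = field(default_factory=list)
    sample_id: str = ""
    purity: Optional[float] = None
    purity_method: Optional[str] = None  # "LUMP" or "external"
    mgmt_status: str = "unknown"

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside [0, 1]")
        if not self.sample_id:
            self.sample_id = f"{self.patient_id}_{self.timepoint}"
        seen = set()
        for v in self.variants:
            if v.key in seen:
                raise ValueError(f"duplicate variant key {v.key} in sample {self.sample_id}")
            seen.add(v.key)

    def keys(self) -> set:
        return {v.key for v in self.variants}

    def by_key(self) -> dict:
        return {v.key: v for v in self.variants}


@dataclass
class PairedCase:
    """One patient's diagnosis/relapse sample pair plus clinical metadata."""

    patient_id: str
    diagnosis: SampleCall
    relapse: SampleCall
    treatment: str = "treated"  # "untreated" | "treated"
    treatment_detail: str = ""
    time_to_recurrence_months: Optional[float] = None
    survival_months: Optional[float] = None
    gender: str = ""
    age_at_diagnosis: Optional[float] = None
    primary_diagnosis: str = ""
    recurrence_diagnosis: str = ""

    def __post_init__(self):
        if self.diagnosis.timepoint != DIAGNOSIS:
            raise ValueError("diagnosis sample has wrong timepoint")
        if self.relapse.timepoint != RELAPSE:
            raise ValueError("relapse sample has wrong timepoint")
        if not (self.diagnosis.patient_id == self.relapse.patient_id == self.patient_id):
            raise ValueError("patient_id mismatch between case and samples")


@dataclass
class MethylationProfile:
    """Per-sample methylation array betas: probe id -> (beta, detection p)."""

    sample_id: str
    probes: dict = field(default_factory=dict)

    def __post_init__(self):
        for probe, (beta, det_p) in self.probes.items():
            if not (0.0 <= beta <= 1.0):
                raise ValueError(f"beta {beta} outside [0, 1] for probe {probe}")
            if not (0.0 <= det_p <= 1.0):
                raise ValueError(f"detection_p {det_p} outside [0, 1] for probe {probe}")


# ---------------------------------------------------------------------------
# parsing helpers

def _opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def _opt_str(s: str) -> Optional[str]:
    return None if s == "" else s


def _opt_bool(s: str) -> Optional[bool]:
    if s == "":
        return None
    if s.lower() in ("1", "true", "t", "yes"):
        return True
    if s.lower() in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse flag value {s!r}")


def _normalize_consequence(s: str) -> str:
    s = s.strip().lower()
    if s == "":
        return "other"
    if s in CONSEQUENCES:
        return s
    log.warning("unknown consequence %r mapped to 'other'", s)
    return "other"


def read_variant_table(path, dialect: str = "tsv") -> dict:
    """Read a variant table into ``{sample_id: SampleCall}``.

    ``dialect`` is ``"tsv"`` (native dialect, default) or ``"vcf"``.
    Malformed rows raise :class:`TableFormatError` naming the line number.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    samples: dict = {}
    meta: dict = {}
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != VARIANT_TABLE_COLUMNS:
                    raise TableFormatError(
                        f"{path}:{lineno}: header does not match the variant "
                        f"table dialect (got {header})"
                    )
                continue
            if len(fields) != len(VARIANT_TABLE_COLUMNS):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(VARIANT_TABLE_COLUMNS)} "
                    f"fields, got {len(fields)}"
                )
            row = dict(zip(VARIANT_TABLE_COLUMNS, fields))
            try:
                rec = VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vaf=float(row["vaf"]),
                    depth=int(row["depth"]),
                    alt_reads=int(row["alt_reads"]),
                    qual=float(row["qual"]),
                    caller_p=float(row["caller_p"]),
                    gene=row["gene"],
                    consequence=_normalize_consequence(row["consequence"]),
                    pop_maf=_opt_float(row["pop_maf"]),
                    context_5p=_opt_str(row["context_5p"]),
                    context_3p=_opt_str(row["context_3p"]),
                    damaging_pred=_opt_bool(row["damaging_pred"]),
                )
            except (ValueError, KeyError) as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
            sid = row["sample_id"]
            samples.setdefault(sid, []).append(rec)
            meta.setdefault(sid, (row["patient_id"], row["timepoint"]))
            if meta[sid] != (row["patient_id"], row["timepoint"]):
                raise TableFormatError(
                    f"{path}:{lineno}: sample {sid} has inconsistent "
                    "patient_id/timepoint"
                )
    out = {}
    for sid, recs in samples.items():
        patient_id, timepoint = meta[sid]
        try:
            out[sid] = SampleCall(
                patient_id=patient_id, timepoint=timepoint,
                variants=recs, sample_id=sid,
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: sample {sid}: {exc}") from exc
    return out


def write_variant_table(samples: Iterable[SampleCall], path) -> None:
    """Write SampleCalls in the native TSV dialect (round-trips exactly)."""

    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("# clonevo variant table; coordinates 1-based, fully closed\n")
        fh.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for sample in samples:
            for v in sample.variants:
                fh.write("\t".join([
                    sample.sample_id, sample.patient_id, sample.timepoint,
                    v.chrom, str(v.pos), v.ref, v.alt, fmt(v.vaf),
                    str(v.depth), str(v.alt_reads), fmt(v.qual),
                    fmt(v.caller_p), v.gene, v.consequence, fmt(v.pop_maf),
                    fmt(v.context_5p), fmt(v.context_3p), fmt(v.damaging_pred),
                ]) + "\n")


def _read_vcf(path) -> dict:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("the VCF dialect requires cyvcf2") from exc

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    per_sample: dict = {s: [] for s in sample_names}
    for rec in vcf:
        gene = rec.INFO.get("GENE") or ""
        conseq = _normalize_consequence(str(rec.INFO.get("CONSEQ") or ""))
        pop_maf = rec.INFO.get("POPMAF")
        dp = rec.format("DP")
        ao = rec.format("AO")
        af = rec.format("AF")
        for i, s in enumerate(sample_names):
            if dp is None or af is None or ao is None:
                continue
            depth = int(dp[i][0])
            alt_reads = int(ao[i][0])
            vaf = float(af[i][0])
            if depth <= 0 or alt_reads < 0 or vaf < 0:
                continue
            per_sample[s].append(VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                vaf=vaf, depth=depth, alt_reads=alt_reads,
                qual=float(rec.QUAL if rec.QUAL is not None else 0.0),
                caller_p=float(rec.INFO.get("CALLERP") or 0.0),
                gene=gene, consequence=conseq,
                pop_maf=float(pop_maf) if pop_maf is not None else None,
            ))
    out = {}
    for s, recs in per_sample.items():
        # sample naming convention "<patient>_<timepoint>"
        if "_" in s and s.rsplit("_", 1)[1] in TIMEPOINTS:
            patient_id, timepoint = s.rsplit("_", 1)
        else:
            patient_id, timepoint = s, DIAGNOSIS
        out[s] = SampleCall(patient_id=patient_id, timepoint=timepoint,
                            variants=recs, sample_id=s)
    return out


def read_cohort_metadata(path) -> list:
    """Read a clinical-cohort TSV into PairedCase skeletons.

    One row per patient; ``treatment`` is ``untreated`` iff
    ``treatment_detail`` equals ``"none"`` (case-insensitive).  Duplicate
    patient ids are an error.  Returned cases carry empty SampleCalls.
    """
    cases = []
    seen = set()
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != COHORT_TABLE_COLUMNS:
                    raise TableFormatError(
                        f"{path}:{lineno}: header does not match the cohort "
                        f"metadata schema (got {header})"
                    )
                continue
            if len(fields) != len(COHORT_TABLE_COLUMNS):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(COHORT_TABLE_COLUMNS)} "
                    f"fields, got {len(fields)}"
                )
            row = dict(zip(COHORT_TABLE_COLUMNS, fields))
            pid = row["patient_id"]
            if pid in seen:
                raise TableFormatError(f"{path}:{lineno}: duplicate patient_id {pid!r}")
            seen.add(pid)
            detail = row["treatment_detail"]
            cases.append(PairedCase(
                patient_id=pid,
                diagnosis=SampleCall(patient_id=pid, timepoint=DIAGNOSIS),
                relapse=SampleCall(patient_id=pid, timepoint=RELAPSE),
                treatment="untreated" if detail.strip().lower() == "none" else "treated",
                treatment_detail=detail,
                time_to_recurrence_months=_opt_float(row["time_to_recurrence_months"]),
                survival_months=_opt_float(row["survival_months"]),
                gender=row["gender"],
                age_at_diagnosis=_opt_float(row["age_at_diagnosis"]),
                primary_diagnosis=row["primary_diagnosis"],
                recurrence_diagnosis=row["recurrence_diagnosis"],
            ))
    return cases


def read_methylation_table(path, sample_id: Optional[str] = None) -> MethylationProfile:
    """Read a 2-3 column methylation TSV: probe, beta[, detection_p].

    A missing ``detection_p`` column defaults to 0 (probe detected).  Betas
    outside [0, 1] are rejected.
    """
    probes = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("probe", "probe_id"):  # optional header
                continue
            if len(fields) not in (2, 3):
                raise TableFormatError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            probe = fields[0]
            beta = float(fields[1])
            det_p = float(fields[2]) if len(fields) == 3 else 0.0
            if not (0.0 <= beta <= 1.0):
                raise TableFormatError(f"{path}:{lineno}: beta {beta} outside [0, 1]")
            if not (0.0 <= det_p <= 1.0):
                raise TableFormatError(f"{path}:{lineno}: detection_p {det_p} outside [0, 1]")
            probes[probe] = (beta, det_p)
    if sample_id is None:
        sample_id = Path(path).stem
        if sample_id.startswith("methylation_"):
            sample_id = sample_id[len("methylation_"):]
    return MethylationProfile(sample_id=sample_id, probes=probes)


def write_methylation_table(profile: MethylationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe\tbeta\tdetection_p\n")
        for probe, (beta, det_p) in profile.probes.items():
            fh.write(f"{probe}\t{beta!r}\t{det_p!r}\n")


def load_builtin_cohort() -> list:
    """The built-in 21-patient paired-GBM clinical table as PairedCase skeletons."""
    with resources.as_file(
        resources.files("clonevo.data") / "paired_gbm_cohort.tsv"
    ) as p:
        return read_cohort_metadata(p)
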