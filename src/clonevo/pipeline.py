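"""End-to-end orchestration: simulate-or-read -> filter -> purity gate ->
VAF adjustment -> partition -> spectrum -> neutral fits -> paired shift ->
report bundle.

Stage order is fixed: per-variant quality filters, cohort artifact
exclusion, purity gating, VAF adjustment, subclonal windowing.  Every
threshold applied is recorded in the run log so a run is auditable, and two
runs with the same configuration and seed produce byte-identical bundles
(the log carries no timestamps).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import methylation_purity as mp
from . import neutral_evolution as ne
from .mutational_spectrum import (
    HypermutatorConfig,
    call_hypermutator,
    spectrum_counts,
)
from .paired_comparison import (
    burden_summary,
    clinical_summary,
    detect_burden_outliers,
    partition_shared_unique,
)
from .quality_filters import (
    FilterConfig,
    apply_quality_filters,
    exclude_recurrent_artifacts,
)
from .synthetic_cohort import CohortSimConfig, generate_cohort
from .variant_model import (
    DIAGNOSIS,
    RELAPSE,
    MethylationProfile,
    PairedCase,
    SampleCall,
    read_cohort_metadata,
    read_methylation_table,
    read_variant_table,
    write_variant_table,
)


@dataclass
class PipelineConfig:
    # exactly one input source: either the three paths, or a simulation config
    variants_path: Optional[str] = None
    metadata_path: Optional[str] = None
    methylation_dir: Optional[str] = None
    sim: Optional[CohortSimConfig] = None

    filters: FilterConfig = field(default_factory=FilterConfig)
    hypermutator: HypermutatorConfig = field(default_factory=HypermutatorConfig)
    f_min: float = ne.F_MIN_DEFAULT
    f_max: float = ne.F_MAX_DEFAULT
    r2_threshold: float = ne.R2_THRESHOLD_DEFAULT
    min_variants: int = 2
    inclusive_low: bool = False           # public-data window reading
    min_purity: float = 0.55
    purity_source: str = "lump"           # "lump" | "external"
    outdir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        has_paths = self.variants_path is not None
        if has_paths == (self.sim is not None):
            raise ValueError("configure exactly one input source (paths or sim)")
        if self.purity_source not in ("lump", "external"):
            raise ValueError("purity_source must be 'lump' or 'external'")


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        sim_cfg = cfg.sim if cfg.sim.seed else CohortSimConfig(
            **{**asdict(cfg.sim), "seed": cfg.seed})
        cases, profiles, truths = generate_cohort(sim_cfg)
        return cases, profiles, truths
    samples = read_variant_table(cfg.variants_path)
    skeletons = read_cohort_metadata(cfg.metadata_path) if cfg.metadata_path else []
    by_patient: Dict[str, Dict[str, SampleCall]] = {}
    for s in samples.values():
        by_patient.setdefault(s.patient_id, {})[s.timepoint] = s
    meta = {c.patient_id: c for c in skeletons}
    cases = []
    for pid, tp in sorted(by_patient.items()):
        if DIAGNOSIS not in tp or RELAPSE not in tp:
            raise ValueError(f"patient {pid} lacks a complete diagnosis/relapse pair")
        skel = meta.get(pid)
        cases.append(PairedCase(
            patient_id=pid, diagnosis=tp[DIAGNOSIS], relapse=tp[RELAPSE],
            treatment=skel.treatment if skel else "treated",
            treatment_detail=skel.treatment_detail if skel else "",
            time_to_recurrence_months=(
                skel.time_to_recurrence_months if skel else None),
            survival_months=skel.survival_months if skel else None,
        ))
    profiles: Dict[str, MethylationProfile] = {}
    if cfg.methylation_dir:
        for p in sorted(Path(cfg.methylation_dir).glob("methylation_*.tsv")):
            prof = read_methylation_table(p)
            profiles[prof.sample_id] = prof
    return cases, profiles, None


def _fit_to_dict(fit: ne.NeutralFitResult) -> dict:
    return {
        "source": fit.source,
        "slope": fit.slope,
        "r_squared": None if math.isnan(fit.r_squared) else fit.r_squared,
        "n_variants": fit.n_variants,
        "classification": fit.classification,
        "flagged_single_point_influence": fit.flagged_single_point_influence,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the cohort summary (also written to disk
    when ``cfg.outdir`` is set)."""
    log_lines: List[str] = []

    def logmsg(msg: str) -> None:
        log_lines.append(msg)

    cases, profiles, truths = _load_inputs(cfg)
    logmsg(f"loaded {len(cases)} paired cases, {len(profiles)} methylation profiles")

    # 1. per-variant quality filters
    f = cfg.filters
    logmsg(
        "quality filters: caller_p<%g qual>=%g depth>%d alt_reads>=%d "
        "vaf>=%g pop_maf<=%g" % (f.max_caller_p, f.min_qual, f.min_depth,
                                 f.min_alt_reads, f.min_vaf, f.max_pop_maf))
    filter_reports = {}
    filtered_samples: List[SampleCall] = []
    for case in cases:
        for sample in (case.diagnosis, case.relapse):
            out, rep = apply_quality_filters(sample, f)
            filter_reports[sample.sample_id] = rep
            filtered_samples.append(out)

    # 2. cohort-level artifact exclusion
    filtered_samples, removed_keys = exclude_recurrent_artifacts(filtered_samples, f)
    logmsg(f"artifact exclusion (> {f.max_patient_fraction:.0%} of patients): "
           f"{len(removed_keys)} keys removed")
    by_sid = {s.sample_id: s for s in filtered_samples}
    cases = [
        PairedCase(
            patient_id=c.patient_id,
            diagnosis=by_sid[c.diagnosis.sample_id],
            relapse=by_sid[c.relapse.sample_id],
            treatment=c.treatment, treatment_detail=c.treatment_detail,
            time_to_recurrence_months=c.time_to_recurrence_months,
            survival_months=c.survival_months,
        )
        for c in cases
    ]

    # 3. purity estimation + gate
    purity_info = {}
    gated: Dict[str, bool] = {}
    purities: Dict[str, float] = {}
    for case in cases:
        for sample in (case.diagnosis, case.relapse):
            sid = sample.sample_id
            est = None
            if cfg.purity_source == "lump" and sid in profiles:
                try:
                    est = mp.lump_purity(profiles[sid])
                except ValueError:
                    est = None
            if est is None and sample.purity is not None:
                est = mp.PurityEstimate(sample.purity, 0, "external")
            if est is None:
                purity_info[sid] = {"purity": None, "method": None, "gate": "exclude"}
                gated[sid] = False
                continue
            gate = mp.purity_gate(est, cfg.min_purity)
            purity_info[sid] = {"purity": est.purity, "method": est.method,
                                "gate": gate}
            gated[sid] = gate == "include"
            purities[sid] = est.purity
    logmsg(f"purity gate at >= {cfg.min_purity}: "
           f"{sum(gated.values())}/{len(gated)} samples included")

    # MGMT calls where methylation data exists
    mgmt_calls = {sid: mp.mgmt_methylation_call(prof)
                  for sid, prof in sorted(profiles.items())}

    # 4. paired partition / burden / outliers
    outliers = detect_burden_outliers(cases) if len(cases) >= 3 else []
    burden = burden_summary(cases, excluded_patients=outliers)
    coding = burden_summary(cases, consequence_subset=("nonsynonymous", "splice_site"),
                            excluded_patients=outliers)
    logmsg(f"burden outliers (Grubbs on relapse-unique counts): {outliers}")

    # 5. spectra on relapse-unique SNVs + hypermutator calls
    unique_relapse_counts = [
        len(partition_shared_unique(c).unique_relapse) for c in cases]
    spectra = {}
    hyper = {}
    for case in cases:
        part = partition_shared_unique(case)
        rel = case.relapse.by_key()
        spec = spectrum_counts([rel[k] for k in part.unique_relapse])
        spectra[case.patient_id] = {
            "classes": spec.classes, "ct_contexts": spec.ct_contexts,
            "ct_unresolved": spec.ct_unresolved, "n_non_snv": spec.n_non_snv,
        }
        call = call_hypermutator(case, unique_relapse_counts, cfg.hypermutator)
        hyper[case.patient_id] = {
            "decision": call.decision,
            "n_unique_relapse_snvs": call.n_unique_relapse_snvs,
            "ct_fraction": call.ct_fraction,
            "cpc_cpt_fraction": call.cpc_cpt_fraction,
            "burden_outlier": call.burden_outlier,
        }

    # 6. neutral-evolution fits on purity-adjusted VAFs of gated samples
    windowed: Dict[str, ne.SubclonalSet] = {}
    fits: Dict[str, ne.NeutralFitResult] = {}
    for case in cases:
        for sample in (case.diagnosis, case.relapse):
            sid = sample.sample_id
            if not gated.get(sid):
                continue
            rho = purities[sid]
            adj = [mp.adjust_vaf(v.vaf, rho) for v in sample.variants if v.is_snv]
            sub = ne.subclonal_window(adj, cfg.f_min, cfg.f_max,
                                      inclusive_low=cfg.inclusive_low, source=sid)
            windowed[sid] = sub
            fits[sid] = ne.fit_sample(
                adj, cfg.f_min, cfg.f_max, cfg.r2_threshold,
                cfg.min_variants, cfg.inclusive_low, source=sid)
    logmsg(f"subclonal window ({cfg.f_min}, {cfg.f_max})"
           f"{' inclusive-low' if cfg.inclusive_low else ''}, "
           f"R^2 threshold {cfg.r2_threshold} (strict)")

    def _pool(timepoint: str) -> Optional[dict]:
        sets = [windowed[c.__getattribute__(timepoint).sample_id]
                for c in cases
                if c.__getattribute__(timepoint).sample_id in windowed]
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            return None
        fit = ne.pooled_fit(sets, cfg.r2_threshold, cfg.min_variants)
        d = _fit_to_dict(fit)
        d["source"] = f"pooled_{timepoint}"
        return d

    triples = [
        (c.patient_id, fits[c.diagnosis.sample_id], fits[c.relapse.sample_id])
        for c in cases
        if c.diagnosis.sample_id in fits and c.relapse.sample_id in fits
    ]
    shift = ne.paired_shift_summary(triples)

    summary = {
        "schema_version": 1,
        "seed": cfg.seed,
        "n_patients": len(cases),
        "filter_reports": {
            sid: {"kept": r.kept, "removed": dict(r.removed)}
            for sid, r in sorted(filter_reports.items())
        },
        "artifact_keys_removed": len(removed_keys),
        "purity": dict(sorted(purity_info.items())),
        "mgmt": mgmt_calls,
        "burden": {
            "per_patient": burden.drop(columns=[]).to_dict(orient="records"),
            "group_means": {
                g: {k: float(v) for k, v in row.items()}
                for g, row in burden.attrs["group_means"].iterrows()
            },
            "outlier_patients": outliers,
        },
        "coding_burden": {
            "per_patient": coding.to_dict(orient="records"),
            "group_means": {
                g: {k: float(v) for k, v in row.items()}
                for g, row in coding.attrs["group_means"].iterrows()
            },
        },
        "clinical": clinical_summary(cases),
        "spectrum_unique_relapse": spectra,
        "hypermutator": hyper,
        "neutral": {
            "per_sample": [_fit_to_dict(fits[sid]) for sid in sorted(fits)],
            "pooled_diagnosis": _pool("diagnosis"),
            "pooled_relapse": _pool("relapse"),
            "paired_shift": {
                "per_patient": shift.per_patient,
                "n_pairs": shift.n_pairs,
                "n_decreased": shift.n_decreased,
            },
        },
        "log": log_lines,
    }
    if truths is not None:
        summary["simulation_truth"] = [
            {"patient_id": t.patient_id, "treated": t.treated,
             "hypermutator": t.hypermutator,
             "purity_diagnosis": t.purity_diagnosis,
             "purity_relapse": t.purity_relapse}
            for t in truths
        ]

    if cfg.outdir is not None:
        write_report(summary, cfg.outdir, filtered_samples)
    return summary


def _round_floats(obj, r2_dp: int = 4):
    """Display copy: R^2-like values to 4 decimals, others untouched."""
    if isinstance(obj, dict):
        return {
            k: (round(v, r2_dp) if isinstance(v, float) and (
                k.startswith("r2") or k in ("r_squared",)) and not math.isnan(v)
                else _round_floats(v, r2_dp))
            for k, v in obj.items()
        }
    if isinstance(obj, list):
        return [_round_floats(v, r2_dp) for v in obj]
    return obj


def write_report(summary: dict, outdir, samples: Sequence[SampleCall] = ()) -> None:
    """JSON at full precision plus a display text table with rounded values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if samples:
        write_variant_table(samples, outdir / "filtered_variants.tsv")
    disp = _round_floats(summary)
    lines = ["clonevo cohort report", "====================", ""]
    lines.append(f"patients: {summary['n_patients']}")
    for grp, d in summary["clinical"].items():
        med = d["median_time_to_recurrence_months"]
        lines.append(
            f"{grp}: n={d['n']}, median time to recurrence = "
            f"{'NA' if med is None else f'{med:g} months'}")
    nd = disp["neutral"]
    for key in ("pooled_diagnosis", "pooled_relapse"):
        fit = nd[key]
        if fit:
            lines.append(f"{key}: R^2={fit['r_squared']} slope={fit['slope']:.3g} "
                         f"n={fit['n_variants']} -> {fit['classification']}")
    ps = nd["paired_shift"]
    lines.append(f"paired R^2 decreased at relapse: {ps['n_decreased']} of {ps['n_pairs']}")
    pos = [p for p, h in summary["hypermutator"].items() if h["decision"] == "positive"]
    lines.append(f"hypermutator-positive: {pos if pos else 'none'}")
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(summary["log"]) + "\n")
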