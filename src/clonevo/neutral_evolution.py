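"""The neutral-evolution 1/f test on subclonal VAF distributions.

Under neutral exponential growth the cumulative number of subclonal
mutations with allelic frequency at least f is

    M(f) = (mu/beta) * (1/f - 1/f_max),

i.e. linear in 1/f with zero intercept at f = f_max, where mu/beta is the
effective mutation rate per effective cell division.  The test fits this
line through the origin on the purity-adjusted VAFs inside the subclonal
window (f_min, f_max) — default (0.10, 0.25), strict on both sides, so that
clonal events, ploidy artifacts and low-MAF germline variants (all at
higher frequency) and unreliably detected rare variants (lower frequency)
are excluded — and classifies a sample as evolving neutrally when the
goodness-of-fit R^2 exceeds a stringent threshold (default 0.98, strict).

R^2 is computed about the mean of M, so a terrible fit can give R^2 < 0;
this is intentional and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

F_MIN_DEFAULT = 0.10
F_MAX_DEFAULT = 0.25
R2_THRESHOLD_DEFAULT = 0.98

NEUTRAL = "neutral"
NON_NEUTRAL = "non_neutral"
INSUFFICIENT = "insufficient"


@dataclass
class SubclonalSet:
    """Purity-adjusted VAFs inside the subclonal window for one sample or a pool."""

    adjusted_vafs: List[float]
    f_min: float = F_MIN_DEFAULT
    f_max: float = F_MAX_DEFAULT
    source: str = ""
    inclusive_low: bool = False

    def __post_init__(self):
        if self.inclusive_low:
            bad = [f for f in self.adjusted_vafs
                   if not (self.f_min <= f < self.f_max)]
        else:
            bad = [f for f in self.adjusted_vafs
                   if not (self.f_min < f < self.f_max)]
        if bad:
            raise ValueError(
                f"{len(bad)} frequencies outside the window "
                f"({self.f_min}, {self.f_max})"
            )

    def __len__(self) -> int:
        return len(self.adjusted_vafs)


@dataclass(frozen=True)
class NeutralFitResult:
    slope: float
    r_squared: float
    n_variants: int
    classification: str
    flagged_single_point_influence: bool = False
    source: str = ""


def subclonal_window(
    adjusted_vafs: Sequence[float],
    f_min: float = F_MIN_DEFAULT,
    f_max: float = F_MAX_DEFAULT,
    inclusive_low: bool = False,
    source: str = "",
) -> SubclonalSet:
    """Select frequencies strictly inside (f_min, f_max).

    ``inclusive_low=True`` switches the lower bound to >=, the reading used
    for shallower public-cohort data; the default is strict on both sides.
    """
    vals = np.asarray(adjusted_vafs, dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("adjusted VAFs must lie in [0, 1]")
    if inclusive_low:
        keep = (vals >= f_min) & (vals < f_max)
    else:
        keep = (vals > f_min) & (vals < f_max)
    return SubclonalSet(
        adjusted_vafs=[float(v) for v in vals[keep]],
        f_min=f_min, f_max=f_max, source=source, inclusive_low=inclusive_low,
    )


def cumulative_mf(s: SubclonalSet) -> Tuple[np.ndarray, np.ndarray]:
    """Ordered pairs (x_i, M_i) of the cumulative distribution.

    Frequencies are sorted descending; M_i = i is the count of mutations
    with frequency >= f_(i); x_i = 1/f_(i) - 1/f_max.  Ties share the same
    x but occupy distinct consecutive ranks (stable).
    """
    if len(s) == 0:
        raise ValueError("empty subclonal set")
    f = np.sort(np.asarray(s.adjusted_vafs, dtype=float))[::-1]
    x = 1.0 / f - 1.0 / s.f_max
    m = np.arange(1, f.size + 1, dtype=float)
    return x, m


def _origin_fit(x: np.ndarray, m: np.ndarray) -> Tuple[float, float]:
    """Zero-intercept least squares of M on x; returns (slope, r_squared)."""
    sxx = float(np.dot(x, x))
    slope = max(0.0, float(np.dot(x, m)) / sxx) if sxx > 0 else 0.0
    resid = m - slope * x
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, r2


def classify_evolution(
    r_squared: float,
    n_variants: int,
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    min_variants: int = 2,
) -> str:
    """Neutral iff R^2 strictly exceeds the threshold and n is sufficient."""
    if n_variants < min_variants:
        return INSUFFICIENT
    return NEUTRAL if r_squared > r2_threshold else NON_NEUTRAL


def fit_neutral_model(
    pairs: Tuple[np.ndarray, np.ndarray],
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    min_variants: int = 2,
    source: str = "",
) -> NeutralFitResult:
    """Fit M = slope * x through the origin and classify the sample.

    Requires at least two distinct x values; otherwise the result is
    ``insufficient``.  For small samples (n < 10) the fit is additionally
    checked for single-point influence: if dropping any one point flips the
    classification the result is flagged for scrutiny.
    """
    x, m = (np.asarray(pairs[0], dtype=float), np.asarray(pairs[1], dtype=float))
    if x.shape != m.shape:
        raise ValueError("x and M must have equal length")
    n = x.size
    if n < 2 or np.unique(x).size < 2:
        return NeutralFitResult(
            slope=0.0, r_squared=float("nan"), n_variants=n,
            classification=INSUFFICIENT, source=source,
        )
    slope, r2 = _origin_fit(x, m)
    cls = classify_evolution(r2, n, r2_threshold, min_variants)
    flagged = False
    if n < 10:
        for i in range(n):
            xi = np.delete(x, i)
            mi = np.delete(m, i)
            if np.unique(xi).size < 2:
                continue
            _, r2_i = _origin_fit(xi, mi)
            if classify_evolution(r2_i, n - 1, r2_threshold,
                                  min(min_variants, n - 1)) != cls:
                flagged = True
                break
    return NeutralFitResult(
        slope=slope, r_squared=r2, n_variants=n, classification=cls,
        flagged_single_point_influence=flagged, source=source,
    )


def fit_sample(
    adjusted_vafs: Sequence[float],
    f_min: float = F_MIN_DEFAULT,
    f_max: float = F_MAX_DEFAULT,
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    min_variants: int = 2,
    inclusive_low: bool = False,
    source: str = "",
) -> NeutralFitResult:
    """Window + cumulative distribution + origin fit in one call."""
    s = subclonal_window(adjusted_vafs, f_min, f_max,
                         inclusive_low=inclusive_low, source=source)
    if len(s) == 0:
        return NeutralFitResult(0.0, float("nan"), 0, INSUFFICIENT, source=source)
    return fit_neutral_model(cumulative_mf(s), r2_threshold, min_variants,
                             source=source)


def pooled_fit(
    samples: Sequence[SubclonalSet],
    r2_threshold: float = R2_THRESHOLD_DEFAULT,
    min_variants: int = 2,
) -> NeutralFitResult:
    """Collective fit: concatenate all samples' windowed VAFs and fit once.

    All sets must share the same window bounds.
    """
    samples = [s for s in samples if len(s) > 0]
    if not samples:
        raise ValueError("no non-empty subclonal sets to pool")
    windows = {(s.f_min, s.f_max, s.inclusive_low) for s in samples}
    if len(windows) != 1:
        raise ValueError(f"mixed subclonal windows cannot be pooled: {windows}")
    f_min, f_max, inclusive_low = windows.pop()
    pooled = SubclonalSet(
        adjusted_vafs=[f for s in samples for f in s.adjusted_vafs],
        f_min=f_min, f_max=f_max, source="pooled", inclusive_low=inclusive_low,
    )
    return fit_neutral_model(cumulative_mf(pooled), r2_threshold, min_variants,
                             source="pooled")


@dataclass
class PairedShiftSummary:
    per_patient: List[dict] = field(default_factory=list)
    n_pairs: int = 0
    n_decreased: int = 0


def paired_shift_summary(
    fits: Sequence[Tuple[str, NeutralFitResult, NeutralFitResult]]
) -> PairedShiftSummary:
    """Diagnosis -> relapse R^2 shift over patients with fits at both timepoints.

    ``fits`` holds (patient_id, diagnosis fit, relapse fit) triples; pairs
    where either fit is ``insufficient`` are skipped.
    """
    out = PairedShiftSummary()
    for patient_id, fd, fr in fits:
        if fd.classification == INSUFFICIENT or fr.classification == INSUFFICIENT:
            continue
        decreased = bool(fr.r_squared < fd.r_squared)
        out.per_patient.append({
            "patient_id": patient_id,
            "r2_diagnosis": fd.r_squared,
            "r2_relapse": fr.r_squared,
            "decreased": decreased,
        })
        out.n_pairs += 1
        out.n_decreased += int(decreased)
    return out
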