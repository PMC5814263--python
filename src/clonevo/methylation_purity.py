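"""Methylation-based tumor purity (LUMP), MGMT promoter calls, purity gating,
and contamination-corrected VAFs.

LUMP (leukocytes-unmethylation-for-purity) exploits a panel of CpG sites that
are unmethylated in leukocytes but methylated in tumor cells: the mean beta
over the informative panel probes, rescaled by a saturation constant
(default 0.85) and capped at 1, estimates the tumor-cell fraction.  Probes
whose detection p-value is not below the threshold are dropped as
uninformative.

The authors of the purity method did not publish the exact probe panel used
here; :data:`DEFAULT_LUMP_PANEL` is a synthetic placeholder panel of 44 probe
ids used by the simulator and the tests.  Real analyses should pass their
own panel.

VAF adjustment assumes copy-neutral diploid admixture: a heterozygous
mutation in a fraction ``c`` of tumor cells at purity ``rho`` is observed at
VAF ``rho*c/2``, so dividing by ``rho`` recovers the purity-free scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_model import MethylationProfile

log = logging.getLogger(__name__)

# Synthetic placeholder panel (44 probes); not the published LUMP panel.
DEFAULT_LUMP_PANEL = tuple(f"cgSIM{i:05d}" for i in range(1, 45))

MGMT_SENTINEL_PROBE = "cg12981137"
# Synthetic placeholder ids for the 12 MGMT promoter-region probes.
DEFAULT_MGMT_PROMOTER_PROBES = tuple(f"cgMGMT{i:03d}" for i in range(1, 13))

LUMP_SCALE = 0.85


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    n_probes_used: int
    method: str  # "LUMP" | "external"

    def __post_init__(self):
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside [0, 1]")


def lump_purity(
    profile: MethylationProfile,
    probe_panel: Sequence[str] = DEFAULT_LUMP_PANEL,
    detection_p_threshold: float = 0.05,
    scale: float = LUMP_SCALE,
) -> PurityEstimate:
    """LUMP purity: min(1, mean beta over informative panel probes / scale).

    Informative probes are panel members present in the profile with
    detection p-value strictly below the threshold.  Zero informative
    probes is an error.
    """
    if not probe_panel:
        raise ValueError("empty probe panel")
    betas = [
        profile.probes[p][0] for p in probe_panel
        if p in profile.probes and profile.probes[p][1] < detection_p_threshold
    ]
    if not betas:
        raise ValueError(
            f"no informative probes for sample {profile.sample_id}: "
            "all panel probes missing or failing detection p"
        )
    purity = min(1.0, float(np.mean(betas)) / scale)
    return PurityEstimate(purity=purity, n_probes_used=len(betas), method="LUMP")


def mgmt_methylation_call(
    profile: MethylationProfile,
    sentinel_probe: str = MGMT_SENTINEL_PROBE,
    promoter_probes: Sequence[str] = DEFAULT_MGMT_PROMOTER_PROBES,
    beta_threshold: float = 0.2,
) -> str:
    """MGMT promoter methylation call.

    ``methylated`` iff the sentinel probe beta exceeds the threshold
    (strictly) AND the mean beta over the available promoter probes also
    exceeds it; ``unmethylated`` when either condition fails;
    ``indeterminate`` when the sentinel probe is missing.
    """
    if sentinel_probe not in profile.probes:
        log.warning("sample %s: MGMT sentinel probe %s missing -> indeterminate",
                    profile.sample_id, sentinel_probe)
        return "indeterminate"
    sentinel_beta = profile.probes[sentinel_probe][0]
    promoter_betas = [profile.probes[p][0] for p in promoter_probes
                      if p in profile.probes]
    if not promoter_betas:
        log.warning("sample %s: no MGMT promoter probes present -> indeterminate",
                    profile.sample_id)
        return "indeterminate"
    if sentinel_beta > beta_threshold and float(np.mean(promoter_betas)) > beta_threshold:
        return "methylated"
    return "unmethylated"


def purity_gate(estimate: PurityEstimate, min_purity: float = 0.55) -> str:
    """``include`` iff purity >= min_purity (normal contamination <= 45%)."""
    return "include" if estimate.purity >= min_purity else "exclude"


def adjust_vaf(vaf: float, purity: float) -> float:
    """Correct an observed VAF for normal-cell contamination.

    ``adjusted = min(1, vaf / purity)`` under the copy-neutral diploid
    admixture model.  Zero purity is an error.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    return min(1.0, vaf / purity)
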