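"""Ground-truth clonal-growth simulator for paired tumor samples.

A discrete-generation Galton-Watson branching process: every cell produces
two daughters per generation, each daughter independently survives with
probability ``1 - death_prob`` and acquires ``Poisson(mu)`` novel mutations.
Growth stops once the population reaches ``n_final``.  Under neutrality this
realizes the 1/f subclonal spectrum: the expected number of mutations at
cell fraction >= phi grows linearly in 1/phi with slope

    mu * m / (m - 1),        m = 2 * (1 - death_prob)

(m is the per-generation growth factor), which on the VAF scale of a
copy-neutral diploid heterozygous tumor becomes ``mu * m / (2 * (m - 1))``
— the mu/beta slope the neutral-evolution fit estimates
(:func:`expected_mf_slope`).

Selection: an advantaged lineage multiplies its division success by
``1 + s``, implemented as ``Poisson(2 * (1 - death_prob) * s)`` *extra*
daughters per cell so the expected offspring count is exactly
``2 * (1 - death_prob) * (1 + s)`` for any s >= 0.

Paired design: the diagnosis sample is drawn from the grown tumor; a
treatment bottleneck then retains each cell with probability
``bottleneck_fraction``, except that in treated patients a designated
small set of pre-existing resistant subclones (polyclonal resistance)
survives with probability ``bottleneck_fraction ** (1 / (1 + s))``
(resistance reduces the log-kill by the factor 1 + s), enriching each to a
distinct intermediate frequency; regrowth to the original size is neutral,
so the partially swept clones persist as non-neutral clusters in the
subclonal window.  Untreated patients get a milder unbiased bottleneck
(surgical debulking alone) and neutral regrowth.  A TMZ-hypermutator patient additionally
receives ``tmz_injection_count`` injected C>T mutations with CpC/CpT
contexts at subclonal cell fractions, unique to the relapse.

Sequencing is emulated per site: depth ~ Poisson(mean depth), alternate
reads ~ Binomial(depth, purity * cell_fraction / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .methylation_purity import (
    DEFAULT_LUMP_PANEL,
    DEFAULT_MGMT_PROMOTER_PROBES,
    LUMP_SCALE,
    MGMT_SENTINEL_PROBE,
)
from .variant_model import (
    DIAGNOSIS,
    RELAPSE,
    COHORT_TABLE_COLUMNS,
    MethylationProfile,
    PairedCase,
    SampleCall,
    VariantRecord,
    write_methylation_table,
    write_variant_table,
)

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_CONSEQUENCES = ("nonsynonymous", "synonymous", "intronic", "splice_site", "other")
_CONSEQUENCE_P = (0.40, 0.15, 0.35, 0.05, 0.05)


class ExtinctionError(RuntimeError):
    """The branching process died out before reaching the target size."""


DEEP_ID_BASE = 10_000_000      # id space for deep-lineage mutations
INJECTED_ID_BASE = 20_000_000  # id space for injected TMZ mutations
_DEEP_INIT_SIZE = 200          # population size at which deep lineages appear


@dataclass(frozen=True)
class SimulationConfig:
    n_final: int = 10_000
    mu: float = 10.0
    death_prob: float = 0.2
    selection_events: Tuple[Tuple[int, float], ...] = ()
    depth: float = 1272.0
    purity: float = 1.0
    seed: int = 0
    ploidy: int = 2  # copy-neutral diploid only
    max_retries: int = 50
    background_spectrum: Tuple[float, ...] = (1 / 6,) * 6
    # Deep-lineage component.  A tractable tree of ~1e4 cells holds only a
    # handful of correlated early lineages in the subclonal window, whereas
    # a full-scale tumor contributes hundreds of independent small lineages
    # there.  The generator therefore supplements the tree with mutations
    # drawn iid from the neutral 1/f^2 law at VAF-scale slope ``deep_rate``
    # (additional mu/beta units), carried as lineage counts through
    # bottlenecks (treatment-sensitive, binomially resampled).
    deep_rate: float = 20.0
    deep_cf_range: Tuple[float, float] = (0.10, 0.90)

    def __post_init__(self):
        if self.n_final < 10:
            raise ValueError("n_final must be >= 10")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if not (0.0 <= self.death_prob < 0.5):
            raise ValueError("death_prob must be in [0, 0.5)")
        if self.ploidy != 2:
            raise ValueError("only copy-neutral diploid (ploidy 2) is modeled")
        if abs(sum(self.background_spectrum) - 1.0) > 1e-9:
            raise ValueError("background_spectrum must sum to 1")


def expected_mf_slope(cfg: SimulationConfig) -> float:
    """Theoretical mu/beta slope of M(f) vs 1/f on the VAF scale.

    The tree contributes mu * m / (2 * (m - 1)) with m the per-generation
    growth factor; the deep-lineage component adds its nominal rate.
    """
    m = 2.0 * (1.0 - cfg.death_prob)
    return cfg.mu * m / (2.0 * (m - 1.0)) + cfg.deep_rate


@dataclass
class SimulatedTumor:
    """Snapshot of a tumor's mutations with ground-truth cell fractions."""

    ids: np.ndarray           # mutation ids (tree node ids; injected ids beyond)
    cell_fraction: np.ndarray
    sub_class: np.ndarray     # one of the six pyrimidine classes, per mutation
    context_5p: np.ndarray
    context_3p: np.ndarray
    consequence: np.ndarray
    origin: np.ndarray        # "growth" | "injected_tmz"
    parent: List[int]         # clone-tree parent links for growth mutations
    generations: int
    population: int


class BranchingTumor:
    """Mutable Galton-Watson tumor; grows, bottlenecks, and snapshots."""

    def __init__(self, cfg: SimulationConfig, rng: Optional[np.random.Generator] = None):
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.parent: List[int] = []       # parent mutation id per node, -1 = root
        self.population: Dict[int, int] = {-1: 1}  # genotype node -> cell count
        self.generations = 0
        self.advantaged: Dict[int, float] = {}     # node -> fitness multiplier
        self._fit_memo: Dict[int, float] = {}
        self._pending_events = sorted(cfg.selection_events)
        # lazily extended per-mutation annotations (consistent across snapshots)
        self._ann_rng = np.random.default_rng(self.rng.integers(2**31))
        self._ann_class = np.empty(0, dtype="U3")
        self._ann_ctx5 = np.empty(0, dtype="U1")
        self._ann_ctx3 = np.empty(0, dtype="U1")
        self._ann_conseq = np.empty(0, dtype="U13")
        # deep-lineage mutations, created at the first snapshot
        self._deep_rng = np.random.default_rng(self.rng.integers(2**31))
        self._deep_carriers: Optional[np.ndarray] = None
        self._deep_ann: Optional[Tuple[np.ndarray, ...]] = None

    # -- fitness ----------------------------------------------------------
    def _fitness(self, node: int) -> float:
        """Multiplicative fitness of a genotype: product over advantaged ancestors."""
        if node == -1:
            return 1.0
        memo = self._fit_memo
        if node in memo:
            return memo[node]
        chain = []
        cur = node
        while cur != -1 and cur not in memo:
            chain.append(cur)
            cur = self.parent[cur]
        f = 1.0 if cur == -1 else memo[cur]
        for n in reversed(chain):
            f = f * self.advantaged.get(n, 1.0)
            memo[n] = f
        return f

    def _boost(self, node: int, s: float) -> None:
        if s > 0 and node != -1:
            self.advantaged[node] = self.advantaged.get(node, 1.0) * (1.0 + s)
            self._fit_memo.clear()

    def _has_ancestor(self, node: int, anc: int) -> bool:
        while node != -1:
            if node == anc:
                return True
            node = self.parent[node]
        return False

    # -- growth -----------------------------------------------------------
    @property
    def size(self) -> int:
        return sum(self.population.values())

    def step(self) -> None:
        """One synchronous generation of division, death and mutation."""
        cfg, rng = self.cfg, self.rng
        p_surv = 1.0 - cfg.death_prob
        p_any_mut = -math.expm1(-cfg.mu)
        new_pop: Dict[int, int] = {}
        for g, c in self.population.items():
            daughters = int(rng.binomial(2 * c, p_surv))
            s_extra = self._fitness(g) - 1.0
            if s_extra > 0:
                daughters += int(rng.poisson(2.0 * p_surv * s_extra * c))
            if daughters == 0:
                continue
            n_mutating = int(rng.binomial(daughters, p_any_mut))
            stay = daughters - n_mutating
            if stay:
                new_pop[g] = new_pop.get(g, 0) + stay
            if n_mutating == 0:
                continue
            k = rng.poisson(cfg.mu, n_mutating)
            while np.any(k == 0):  # zero-truncated: mutating cells carry >= 1
                zero = k == 0
                k[zero] = rng.poisson(cfg.mu, int(zero.sum()))
            parent = self.parent
            for ki in k:
                anc = g
                for _ in range(int(ki)):
                    parent.append(anc)
                    anc = len(parent) - 1
                new_pop[anc] = new_pop.get(anc, 0) + 1
        self.population = new_pop
        self.generations += 1
        if self._deep_carriers is not None:
            # deep lineages grow at the neutral baseline rate
            self._deep_carriers = self._deep_carriers * (2.0 * p_surv)
        if not new_pop:
            raise ExtinctionError(f"population extinct at generation {self.generations}")
        if self._deep_carriers is None and self.size >= _DEEP_INIT_SIZE:
            # instantiate early so later selective sweeps deflate them
            self._ensure_deep()
        size = self.size
        while self._pending_events and size >= self._pending_events[0][0]:
            _, s = self._pending_events.pop(0)
            self._boost(self._random_genotype(), s)

    def _random_genotype(self) -> int:
        nodes = list(self.population)
        counts = np.array([self.population[n] for n in nodes], dtype=float)
        return nodes[int(self.rng.choice(len(nodes), p=counts / counts.sum()))]

    def grow_to(self, n_final: int) -> None:
        guard = 0
        while self.size < n_final:
            self.step()
            guard += 1
            if guard > 10_000:  # pragma: no cover
                raise RuntimeError("growth did not terminate")

    # -- bottleneck -------------------------------------------------------
    def bottleneck(
        self,
        fraction: float,
        resistant_nodes: Optional[Sequence[int]] = None,
        resistant_survival: Optional[float] = None,
    ) -> None:
        """Random survival of each cell; resistant subtrees (if any) survive
        with their own probability and each is guaranteed a survivor."""
        rng = self.rng
        nodes = list(resistant_nodes or ())
        new_pop: Dict[int, int] = {}
        alive = {n: 0 for n in nodes}
        fallback: Dict[int, int] = {}
        for g, c in self.population.items():
            owner = next((n for n in nodes if self._has_ancestor(g, n)), None)
            p = resistant_survival if (owner is not None and resistant_survival is not None) \
                else fraction
            kept = int(rng.binomial(c, p))
            if kept:
                new_pop[g] = kept
                if owner is not None:
                    alive[owner] += kept
            if owner is not None and owner not in fallback:
                fallback[owner] = g
        for n in nodes:
            if alive[n] == 0 and n in fallback:
                new_pop[fallback[n]] = 1  # refractory clone survives treatment
        if not new_pop:
            raise ExtinctionError("bottleneck removed every cell")
        self.population = new_pop
        if self._deep_carriers is not None:
            # deep lineages are treatment-sensitive
            self._deep_carriers = rng.binomial(
                np.round(self._deep_carriers).astype(np.int64), fraction
            ).astype(float)

    # -- snapshots --------------------------------------------------------
    def _extend_annotations(self) -> None:
        n = len(self.parent)
        have = self._ann_class.size
        if n <= have:
            return
        k = n - have
        rng = self._ann_rng
        cls = rng.choice(SIX_CLASSES, size=k, p=self.cfg.background_spectrum)
        self._ann_class = np.concatenate([self._ann_class, cls])
        self._ann_ctx5 = np.concatenate([self._ann_ctx5, rng.choice(_BASES, size=k)])
        self._ann_ctx3 = np.concatenate([self._ann_ctx3, rng.choice(_BASES, size=k)])
        conseq = rng.choice(_CONSEQUENCES, size=k, p=_CONSEQUENCE_P)
        self._ann_conseq = np.concatenate([self._ann_conseq, conseq])

    def _ensure_deep(self) -> None:
        """Create the deep-lineage mutations on the first snapshot."""
        if self._deep_carriers is not None or self.cfg.deep_rate <= 0:
            return
        rng = self._deep_rng
        lo, hi = self.cfg.deep_cf_range
        n_expected = 2.0 * self.cfg.deep_rate * (1.0 / lo - 1.0 / hi)
        k = int(rng.poisson(n_expected))
        # inverse-CDF draw from the neutral law: 1/f uniform on (1/hi, 1/lo)
        phi = 1.0 / rng.uniform(1.0 / hi, 1.0 / lo, size=k)
        self._deep_carriers = phi * self.size
        self._deep_ann = (
            rng.choice(SIX_CLASSES, size=k, p=self.cfg.background_spectrum),
            rng.choice(_BASES, size=k),
            rng.choice(_BASES, size=k),
            rng.choice(_CONSEQUENCES, size=k, p=_CONSEQUENCE_P),
        )

    def snapshot(self) -> SimulatedTumor:
        """Current mutations with cell fractions (carriers / population size)."""
        n_nodes = len(self.parent)
        carriers = np.zeros(n_nodes, dtype=np.int64)
        for g, c in self.population.items():
            if g != -1:
                carriers[g] += c
        parent = self.parent
        for node in range(n_nodes - 1, -1, -1):  # children precede parents
            p = parent[node]
            if p != -1 and carriers[node]:
                carriers[p] += carriers[node]
        popsize = self.size
        present = np.nonzero(carriers)[0]
        self._extend_annotations()
        self._ensure_deep()
        ids = present
        cf = carriers[present] / popsize
        cls = self._ann_class[present]
        ctx5 = self._ann_ctx5[present]
        ctx3 = self._ann_ctx3[present]
        conseq = self._ann_conseq[present]
        origin = np.full(present.size, "growth", dtype="U12")
        if self._deep_carriers is not None and self._deep_carriers.size:
            keep = self._deep_carriers >= 1.0
            deep_cf = np.minimum(1.0, self._deep_carriers[keep] / popsize)
            ids = np.concatenate([ids, DEEP_ID_BASE + np.nonzero(keep)[0]])
            cf = np.concatenate([cf, deep_cf])
            cls = np.concatenate([cls, self._deep_ann[0][keep]])
            ctx5 = np.concatenate([ctx5, self._deep_ann[1][keep]])
            ctx3 = np.concatenate([ctx3, self._deep_ann[2][keep]])
            conseq = np.concatenate([conseq, self._deep_ann[3][keep]])
            origin = np.concatenate(
                [origin, np.full(int(keep.sum()), "growth", dtype="U12")])
        return SimulatedTumor(
            ids=ids,
            cell_fraction=cf,
            sub_class=cls,
            context_5p=ctx5,
            context_3p=ctx3,
            consequence=conseq,
            origin=origin,
            parent=list(self.parent),
            generations=self.generations,
            population=popsize,
        )


def simulate_tumor(cfg: SimulationConfig) -> SimulatedTumor:
    """Grow a tumor to ``cfg.n_final`` cells, retrying on early extinction."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_retries):
        tumor = BranchingTumor(cfg, rng=np.random.default_rng(rng.integers(2**31)))
        try:
            tumor.grow_to(cfg.n_final)
            return tumor.snapshot()
        except ExtinctionError:
            continue
    raise ExtinctionError(f"extinct in {cfg.max_retries} consecutive attempts")


# ---------------------------------------------------------------------------
# sequencing-read emulation

_CLASS_REF_ALT = {c: (c[0], c[2]) for c in SIX_CLASSES}


def sample_reads(
    tumor: SimulatedTumor,
    depth: float,
    purity: float,
    rng: np.random.Generator,
    patient_id: str = "sim",
    timepoint: str = DIAGNOSIS,
    min_emit_alt_reads: int = 5,
) -> SampleCall:
    """Draw sequencing reads over every mutation and emit detected variants.

    Expected VAF is ``purity * cell_fraction / 2`` (heterozygous, diploid,
    copy-neutral).  Site depth is Poisson around the mean; alternate reads
    binomial.  Mutations drawing fewer than ``min_emit_alt_reads`` alternate
    reads fall below the caller's reporting floor and are omitted.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    n = tumor.ids.size
    evaf = purity * tumor.cell_fraction / 2.0
    site_depth = rng.poisson(depth, n)
    ok = site_depth > 0
    alt = np.zeros(n, dtype=np.int64)
    alt[ok] = rng.binomial(site_depth[ok], evaf[ok])
    emit = ok & (alt >= min_emit_alt_reads)
    variants = []
    for i in np.nonzero(emit)[0]:
        ref, alt_base = _CLASS_REF_ALT[str(tumor.sub_class[i])]
        variants.append(VariantRecord(
            chrom="chr1",
            pos=int(tumor.ids[i]) + 1,
            ref=ref,
            alt=alt_base,
            vaf=float(alt[i] / site_depth[i]),
            depth=int(site_depth[i]),
            alt_reads=int(alt[i]),
            qual=40.0,
            caller_p=1e-4,
            consequence=str(tumor.consequence[i]),
            context_5p=str(tumor.context_5p[i]),
            context_3p=str(tumor.context_3p[i]),
        ))
    return SampleCall(
        patient_id=patient_id, timepoint=timepoint, variants=variants,
        purity=purity, purity_method="external",
    )


# ---------------------------------------------------------------------------
# paired cases and cohorts

@dataclass(frozen=True)
class CohortSimConfig:
    n_patients: int = 21
    fraction_untreated: float = 3 / 21
    relapse_selection_s: float = 1.0
    bottleneck_fraction: float = 0.1          # surgical debulking (both arms)
    treated_bottleneck_fraction: float = 0.01  # surgery + chemoradiation kill
    tmz_injection_count: int = 200
    hypermutator_index: Optional[int] = None  # patient index receiving injection
    n_final: int = 10_000
    mu: float = 10.0
    death_prob: float = 0.2
    deep_rate: float = 20.0
    depth: float = 1272.0
    purity_range: Tuple[float, float] = (0.65, 0.95)
    resistant_cf_band: Tuple[float, float] = (0.03, 0.25)
    n_resistant_clones: int = 2  # polyclonal resistance
    resistant_target_fractions: Tuple[float, ...] = (0.46, 0.36)
    injected_cf_range: Tuple[float, float] = (0.20, 0.50)
    mgmt_methylated_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_untreated", "bottleneck_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.relapse_selection_s < 0:
            raise ValueError("relapse_selection_s must be >= 0")


@dataclass
class PatientTruth:
    patient_id: str
    treated: bool
    hypermutator: bool
    purity_diagnosis: float
    purity_relapse: float
    mgmt_methylated: bool
    resistant_nodes: Tuple[int, ...] = ()
    n_injected: int = 0


def _lineage_disjoint(parent: List[int], a: int, b: int) -> bool:
    def is_anc(anc, node):
        while node != -1:
            if node == anc:
                return True
            node = parent[node]
        return False
    return not (is_anc(a, b) or is_anc(b, a))


def _pick_resistant_nodes(
    tumor: SimulatedTumor,
    band: Tuple[float, float],
    bottleneck_fraction: float,
    resistant_survival: float,
    target_fractions: Sequence[float],
) -> List[int]:
    """Choose disjoint pre-existing subclones whose predicted post-bottleneck
    fractions q_i = c_i*p_r / D come closest to the targets.

    Resistance is polyclonal: several independent lineages survive treatment
    and are enriched to distinct subclonal (window) frequencies rather than
    sweeping clonal.  D is the predicted post-bottleneck population fraction,
    updated greedily as clones are chosen.
    """
    if tumor.ids.size == 0:
        return []
    lo, hi = band
    cf = tumor.cell_fraction
    tree = tumor.ids < DEEP_ID_BASE  # resistant clones are tree lineages
    cand = np.nonzero(tree & (cf >= lo) & (cf <= hi))[0]
    if cand.size == 0:
        cand = np.nonzero(tree)[0]
    if cand.size == 0:
        return []
    chosen: List[int] = []
    chosen_idx: List[int] = []
    c_sum = 0.0
    for target in target_fractions:
        denom = (c_sum * resistant_survival
                 + (1.0 - c_sum) * bottleneck_fraction)
        best, best_err = None, np.inf
        for i in cand:
            if i in chosen_idx:
                continue
            node = int(tumor.ids[i])
            if any(not _lineage_disjoint(tumor.parent, node, n) for n in chosen):
                continue
            c = cf[i]
            q = c * resistant_survival / (c * resistant_survival + denom)
            err = abs(q - target)
            if err < best_err:
                best, best_err = i, err
        if best is None:
            break
        chosen.append(int(tumor.ids[best]))
        chosen_idx.append(best)
        c_sum += float(cf[best])
    return chosen


def _inject_tmz(
    tumor: SimulatedTumor, count: int, cf_range: Tuple[float, float],
    rng: np.random.Generator,
) -> SimulatedTumor:
    """Append TMZ-signature mutations (C>T at CpC/CpT) at subclonal fractions."""
    if count == 0:
        return tumor
    ids = np.arange(INJECTED_ID_BASE, INJECTED_ID_BASE + count)
    cf = rng.uniform(*cf_range, size=count)
    # ~3/4 of TMZ-induced C>T fall at CpC/CpT dinucleotides
    ctx3 = rng.choice(["C", "T", "A", "G"], size=count,
                      p=[0.375, 0.375, 0.125, 0.125])
    return SimulatedTumor(
        ids=np.concatenate([tumor.ids, ids]),
        cell_fraction=np.concatenate([tumor.cell_fraction, cf]),
        sub_class=np.concatenate([tumor.sub_class, np.full(count, "C>T", dtype="U3")]),
        context_5p=np.concatenate([tumor.context_5p, rng.choice(_BASES, size=count)]),
        context_3p=np.concatenate([tumor.context_3p, ctx3]),
        consequence=np.concatenate(
            [tumor.consequence, np.full(count, "nonsynonymous", dtype="U13")]),
        origin=np.concatenate([tumor.origin, np.full(count, "injected_tmz", dtype="U12")]),
        parent=tumor.parent,
        generations=tumor.generations,
        population=tumor.population,
    )


def simulate_paired_case(
    cfg: CohortSimConfig,
    index: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PairedCase, PatientTruth]:
    """One patient: grow, sample diagnosis, bottleneck + regrow, sample relapse."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7919 * index)
    patient_id = f"sim{index + 1:02d}"
    n_untreated = round(cfg.n_patients * cfg.fraction_untreated)
    treated = index >= n_untreated
    hyper = treated and cfg.hypermutator_index == index

    sim_cfg = SimulationConfig(
        n_final=cfg.n_final, mu=cfg.mu, death_prob=cfg.death_prob,
        deep_rate=cfg.deep_rate, depth=cfg.depth, seed=int(rng.integers(2**31)),
    )
    tumor = None
    for _ in range(sim_cfg.max_retries):
        t = BranchingTumor(sim_cfg, rng=np.random.default_rng(rng.integers(2**31)))
        try:
            t.grow_to(cfg.n_final)
            tumor = t
            break
        except ExtinctionError:
            continue
    if tumor is None:
        raise ExtinctionError("paired-case growth repeatedly extinct")

    diag_snap = tumor.snapshot()
    purity_d = float(rng.uniform(*cfg.purity_range))
    purity_r = float(rng.uniform(*cfg.purity_range))
    diagnosis = sample_reads(diag_snap, cfg.depth, purity_d, rng,
                             patient_id=patient_id, timepoint=DIAGNOSIS)

    s = cfg.relapse_selection_s if treated else 0.0
    b_frac = cfg.treated_bottleneck_fraction if treated else cfg.bottleneck_fraction
    resistant_nodes: List[int] = []
    resistant_survival = None
    if treated and s > 0:
        resistant_survival = min(1.0, b_frac ** (1.0 / (1.0 + s)))
        resistant_nodes = _pick_resistant_nodes(
            diag_snap, cfg.resistant_cf_band, b_frac, resistant_survival,
            cfg.resistant_target_fractions[:cfg.n_resistant_clones])
    for _ in range(sim_cfg.max_retries):
        try:
            tumor.bottleneck(b_frac, resistant_nodes, resistant_survival)
            break
        except ExtinctionError:
            continue
    # Regrowth is neutral: selection acts through the biased bottleneck, which
    # leaves the resistant subclone at an intermediate (window) frequency.  A
    # continued growth advantage would complete the sweep and paradoxically
    # restore an apparently neutral spectrum.
    tumor.grow_to(cfg.n_final)

    relapse_snap = tumor.snapshot()
    n_injected = cfg.tmz_injection_count if hyper else 0
    relapse_snap = _inject_tmz(relapse_snap, n_injected, cfg.injected_cf_range, rng)
    relapse = sample_reads(relapse_snap, cfg.depth, purity_r, rng,
                           patient_id=patient_id, timepoint=RELAPSE)

    mgmt = bool(rng.random() < cfg.mgmt_methylated_prob) or hyper
    ttr = float(np.round(rng.lognormal(math.log(9.0), 0.45), 0)) if treated \
        else float(np.round(rng.lognormal(math.log(8.0), 0.8), 0))
    surv = float(np.round(ttr + rng.lognormal(math.log(7.0), 0.5), 1))
    case = PairedCase(
        patient_id=patient_id, diagnosis=diagnosis, relapse=relapse,
        treatment="treated" if treated else "untreated",
        treatment_detail="Concomitant RT/TMZ and standard adjuvant TMZ" if treated else "none",
        time_to_recurrence_months=max(1.0, ttr), survival_months=surv,
        gender="F" if rng.random() < 0.5 else "M",
        age_at_diagnosis=float(rng.integers(30, 75)),
        primary_diagnosis="GBM", recurrence_diagnosis="GBM",
    )
    truth = PatientTruth(
        patient_id=patient_id, treated=treated, hypermutator=hyper,
        purity_diagnosis=purity_d, purity_relapse=purity_r,
        mgmt_methylated=mgmt, resistant_nodes=tuple(resistant_nodes),
        n_injected=n_injected,
    )
    return case, truth


def _methylation_for(
    sample: SampleCall, mgmt_methylated: bool, rng: np.random.Generator,
) -> MethylationProfile:
    """Betas consistent with the sample's configured purity (LUMP-invertible)."""
    probes: Dict[str, Tuple[float, float]] = {}
    for p in DEFAULT_LUMP_PANEL:
        beta = float(np.clip(sample.purity * LUMP_SCALE + rng.normal(0, 0.005), 0, 1))
        probes[p] = (beta, 0.001)
    lo, hi = (0.30, 0.60) if mgmt_methylated else (0.01, 0.15)
    probes[MGMT_SENTINEL_PROBE] = (float(rng.uniform(lo, hi)), 0.001)
    for p in DEFAULT_MGMT_PROMOTER_PROBES:
        probes[p] = (float(rng.uniform(lo, hi)), 0.001)
    return MethylationProfile(sample_id=sample.sample_id, probes=probes)


def generate_cohort(
    cfg: CohortSimConfig,
) -> Tuple[List[PairedCase], Dict[str, MethylationProfile], List[PatientTruth]]:
    """In-memory cohort: paired cases, per-sample methylation, ground truth."""
    rng = np.random.default_rng(cfg.seed)
    cases, truths = [], []
    profiles: Dict[str, MethylationProfile] = {}
    for i in range(cfg.n_patients):
        case, truth = simulate_paired_case(
            cfg, i, rng=np.random.default_rng(rng.integers(2**31)))
        cases.append(case)
        truths.append(truth)
        meth_rng = np.random.default_rng(rng.integers(2**31))
        for sample in (case.diagnosis, case.relapse):
            profiles[sample.sample_id] = _methylation_for(
                sample, truth.mgmt_methylated, meth_rng)
    return cases, profiles, truths


def simulate_cohort(cfg: CohortSimConfig, outdir) -> Dict[str, object]:
    """Write the cohort as the three text dialects; reproducible by seed.

    Emits ``variants.tsv``, ``metadata.tsv`` and one ``methylation_<sample>.tsv``
    per sample under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases, profiles, truths = generate_cohort(cfg)

    variants_path = outdir / "variants.tsv"
    write_variant_table(
        [s for c in cases for s in (c.diagnosis, c.relapse)], variants_path)

    metadata_path = outdir / "metadata.tsv"
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(COHORT_TABLE_COLUMNS) + "\n")
        for c in cases:
            fh.write("\t".join([
                c.patient_id, c.gender, f"{c.age_at_diagnosis:.0f}",
                c.primary_diagnosis, c.recurrence_diagnosis, c.treatment_detail,
                f"{c.time_to_recurrence_months:g}", f"{c.survival_months:g}",
            ]) + "\n")

    meth_paths = {}
    for sid, profile in profiles.items():
        p = outdir / f"methylation_{sid}.tsv"
        write_methylation_table(profile, p)
        meth_paths[sid] = p
    return {
        "variants": variants_path,
        "metadata": metadata_path,
        "methylation": meth_paths,
        "truth": truths,
    }
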