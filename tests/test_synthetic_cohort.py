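import numpy as np
import pytest

from clonevo.methylation_purity import lump_purity
from clonevo.neutral_evolution import fit_sample
from clonevo.synthetic_cohort import (
    CohortSimConfig,
    SimulationConfig,
    expected_mf_slope,
    generate_cohort,
    sample_reads,
    simulate_cohort,
    simulate_paired_case,
    simulate_tumor,
)

FAST = dict(n_final=2000, mu=5.0)


class TestSimulateTumor:
    def test_no_mutation_process_yields_no_mutations(self):
        tum = simulate_tumor(SimulationConfig(n_final=500, mu=0.0,
                                              deep_rate=0.0, seed=3))
        assert tum.ids.size == 0

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=17, **FAST)
        a, b = simulate_tumor(cfg), simulate_tumor(cfg)
        assert np.array_equal(a.ids, b.ids)
        assert np.array_equal(a.cell_fraction, b.cell_fraction)
        assert np.array_equal(a.sub_class, b.sub_class)

    def test_fraction_conservation_and_tree_order(self):
        tum = simulate_tumor(SimulationConfig(seed=5, **FAST))
        assert np.all(tum.cell_fraction <= 1.0)
        assert np.all(tum.cell_fraction > 0.0)
        # a child mutation can never outnumber its parent
        frac = dict(zip(tum.ids.tolist(), tum.cell_fraction.tolist()))
        for mid, cf in frac.items():
            if mid >= 10_000_000:
                continue  # deep lineages carry no tree links
            parent = tum.parent[mid]
            if parent != -1 and parent in frac:
                assert cf <= frac[parent] + 1e-12

    def test_population_reached_target(self):
        cfg = SimulationConfig(seed=2, **FAST)
        tum = simulate_tumor(cfg)
        assert tum.population >= cfg.n_final

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_final=5)
        with pytest.raises(ValueError):
            SimulationConfig(death_prob=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(ploidy=3)


class TestSampleReads:
    def test_diploid_clonal_expectation(self, rng):
        tum = simulate_tumor(SimulationConfig(seed=8, **FAST))
        clonal = tum.cell_fraction > 0.999
        if clonal.sum() == 0:
            pytest.skip("no clonal mutation in this realization")
        sc = sample_reads(tum, depth=50_000, purity=1.0, rng=rng)
        by_pos = {v.pos: v for v in sc.variants}
        for mid in tum.ids[clonal]:
            v = by_pos[int(mid) + 1]
            assert v.vaf == pytest.approx(0.5, abs=0.02)

    def test_expected_vaf_scales_with_purity(self, rng):
        tum = simulate_tumor(SimulationConfig(seed=8, **FAST))
        target = tum.ids[np.argmin(np.abs(tum.cell_fraction - 0.4))]
        vafs = []
        for _ in range(40):
            sc = sample_reads(tum, depth=2000, purity=0.5, rng=rng)
            rec = next((v for v in sc.variants if v.pos == int(target) + 1), None)
            if rec:
                vafs.append(rec.vaf)
        cf = float(tum.cell_fraction[tum.ids == target][0])
        assert np.mean(vafs) == pytest.approx(0.5 * cf / 2, rel=0.15)

    def test_guards(self, rng):
        tum = simulate_tumor(SimulationConfig(seed=8, **FAST))
        with pytest.raises(ValueError):
            sample_reads(tum, depth=0, purity=1.0, rng=rng)
        with pytest.raises(ValueError):
            sample_reads(tum, depth=100, purity=0.0, rng=rng)

    def test_records_pass_variant_invariants(self, rng):
        tum = simulate_tumor(SimulationConfig(seed=8, **FAST))
        sc = sample_reads(tum, depth=800, purity=0.8, rng=rng)
        for v in sc.variants:
            assert v.alt_reads <= v.depth
            assert 0 <= v.vaf <= 1


class TestNeutralSpectrum:
    def test_slope_recovery_no_death(self):
        """With death_prob 0 the window slope tracks mu/beta within 30%."""
        slopes = []
        cfg = None
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, death_prob=0.0, n_final=5000)
            tum = simulate_tumor(cfg)
            sc = sample_reads(tum, depth=1000, purity=1.0,
                              rng=np.random.default_rng(seed + 999))
            fit = fit_sample([v.vaf for v in sc.variants])
            if fit.classification != "insufficient":
                slopes.append(fit.slope)
        expected = expected_mf_slope(cfg)
        assert abs(np.median(slopes) - expected) / expected < 0.30

    def test_selection_event_lowers_fit(self):
        """A strong selective sweep distorts the 1/f spectrum."""
        neutral, selected = [], []
        for seed in range(6):
            for target, ev in ((neutral, ()), (selected, ((100, 1.0),))):
                cfg = SimulationConfig(seed=seed, selection_events=ev,
                                       n_final=5000)
                tum = simulate_tumor(cfg)
                sc = sample_reads(tum, depth=1000, purity=1.0,
                                  rng=np.random.default_rng(seed + 7))
                target.append(fit_sample([v.vaf for v in sc.variants]).r_squared)
        assert np.median(selected) < np.median(neutral)


class TestPairedCase:
    def test_full_bottleneck_keeps_diagnosis_variants(self):
        cfg = CohortSimConfig(n_patients=1, fraction_untreated=1.0,
                              bottleneck_fraction=1.0, seed=4,
                              n_final=2000, mu=5.0)
        case, truth = simulate_paired_case(cfg, 0)
        shared = case.diagnosis.keys() & case.relapse.keys()
        # without a bottleneck the relapse re-detects nearly all diagnosis
        # variants (residual loss is sampling noise at the detection floor)
        assert len(shared) >= 0.7 * len(case.diagnosis.keys())

    def test_untreated_has_no_injection_or_bias(self):
        cfg = CohortSimConfig(n_patients=2, fraction_untreated=1.0, seed=4,
                              hypermutator_index=1, n_final=2000, mu=5.0)
        case, truth = simulate_paired_case(cfg, 1)
        assert truth.hypermutator is False
        assert truth.n_injected == 0
        assert truth.resistant_nodes == ()

    def test_injection_accounting(self):
        cfg = CohortSimConfig(n_patients=2, fraction_untreated=0.0, seed=6,
                              hypermutator_index=1, tmz_injection_count=80,
                              n_final=2000, mu=5.0)
        plain, _ = simulate_paired_case(cfg, 0)
        hyper, truth = simulate_paired_case(cfg, 1)
        assert truth.n_injected == 80

        def unique_relapse_ct(case):
            uniq = case.relapse.keys() - case.diagnosis.keys()
            by_key = case.relapse.by_key()
            return sum(1 for k in uniq
                       if {by_key[k].ref, by_key[k].alt} in ({"C", "T"}, {"G", "A"})
                       and by_key[k].ref in "CG")
        # most injected mutations sit above the detection floor
        assert unique_relapse_ct(hyper) >= 0.5 * 80

    def test_treated_resistant_clones_designated(self):
        cfg = CohortSimConfig(n_patients=1, fraction_untreated=0.0, seed=4,
                              n_final=2000, mu=5.0)
        case, truth = simulate_paired_case(cfg, 0)
        assert truth.treated
        assert 1 <= len(truth.resistant_nodes) <= cfg.n_resistant_clones


class TestCohortOutputs:
    def test_cohort_files_reproducible(self, tmp_path):
        cfg = CohortSimConfig(n_patients=2, seed=12, n_final=1500, mu=4.0)
        a = simulate_cohort(cfg, tmp_path / "a")
        b = simulate_cohort(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "variants.tsv").read_bytes() == \
            (tmp_path / "b" / "variants.tsv").read_bytes()
        assert (tmp_path / "a" / "metadata.tsv").read_bytes() == \
            (tmp_path / "b" / "metadata.tsv").read_bytes()

    def test_lump_recovers_configured_purity(self):
        cfg = CohortSimConfig(n_patients=2, seed=12, n_final=1500, mu=4.0)
        cases, profiles, truths = generate_cohort(cfg)
        for case, truth in zip(cases, truths):
            est = lump_purity(profiles[case.diagnosis.sample_id])
            assert est.purity == pytest.approx(truth.purity_diagnosis, abs=0.02)

    def test_untreated_count_from_fraction(self):
        cfg = CohortSimConfig(n_patients=10, fraction_untreated=0.2, seed=12,
                              n_final=1000, mu=3.0)
        cases, _, _ = generate_cohort(cfg)
        assert sum(c.treatment == "untreated" for c in cases) == 2

    def test_metadata_mirrors_clinical_schema(self, tmp_path):
        from clonevo.variant_model import read_cohort_metadata
        cfg = CohortSimConfig(n_patients=3, seed=12, n_final=1000, mu=3.0)
        paths = simulate_cohort(cfg, tmp_path)
        cases = read_cohort_metadata(paths["metadata"])
        assert len(cases) == 3
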