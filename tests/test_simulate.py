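"""Synthetic-data generators: determinism, inverse construction, recovery."""

import numpy as np
import pytest

from pcfkit import edx, heme, isotope, iv, morphometry, reference, simulate
from pcfkit.errors import InvalidInputError

GS = reference.strain_geometry("GS")
NI = reference.NI_ISOTOPE_REFERENCE


class TestIVSweeps:
    def test_noise_free_sweeps_recover_sigma_exactly(self):
        spec = simulate.IVSimSpec(seed=1, n=10, noise_fraction=0.0, lod_fraction=0.0)
        sweeps, _ = simulate.gen_iv_sweeps(spec, GS)
        area = iv.resolve_area_nm2(GS)
        for s in sweeps:
            res = iv.conductivity(iv.fit_iv(s), s, area)
            assert res.sigma_s_per_cm == pytest.approx(4.0, rel=1e-9)

    def test_same_seed_identical_tables(self):
        spec = simulate.IVSimSpec(seed=5, n=20, lod_fraction=0.1)
        s1, t1 = simulate.gen_iv_sweeps(spec, GS)
        s2, t2 = simulate.gen_iv_sweeps(spec, GS)
        assert t1.equals(t2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.currents, b.currents)
            assert a.gap_length_um == b.gap_length_um

    def test_cohort_mean_recovers_truth_within_two_percent(self):
        spec = simulate.IVSimSpec(seed=7, n=200, true_sigma_s_per_cm=4.0,
                                  noise_fraction=0.05)
        sweeps, _ = simulate.gen_iv_sweeps(spec, GS)
        area = iv.resolve_area_nm2(GS)
        results = [iv.conductivity(iv.fit_iv(s), s, area) for s in sweeps]
        summary = iv.summarize_cohort(results)
        assert abs(summary.mean - 4.0) / 4.0 <= 0.02

    def test_below_lod_sweeps_are_censored_at_requested_rate(self):
        spec = simulate.IVSimSpec(seed=3, n=100, lod_fraction=0.25)
        sweeps, truth = simulate.gen_iv_sweeps(spec, GS)
        area = iv.resolve_area_nm2(GS)
        results = [iv.conductivity(iv.fit_iv(s), s, area) for s in sweeps]
        n_censored = sum(r.below_lod for r in results)
        assert n_censored == int(truth["below_lod"].sum()) == 25

    @pytest.mark.parametrize("true_sigma", [0.1, 1.0, 25.0])
    def test_parameter_recovery_across_conductivity_range(self, true_sigma):
        spec = simulate.IVSimSpec(seed=31, n=100, true_sigma_s_per_cm=true_sigma,
                                  noise_fraction=0.05)
        sweeps, _ = simulate.gen_iv_sweeps(spec, GS)
        area = iv.resolve_area_nm2(GS)
        results = [iv.conductivity(iv.fit_iv(s), s, area) for s in sweeps]
        summary = iv.summarize_cohort(results)
        assert abs(summary.mean - true_sigma) / true_sigma <= 0.05

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate.IVSimSpec(lod_fraction=1.5)


class TestEDXCounts:
    def test_expectation_mode_round_trips_exactly(self):
        spec = simulate.EDXSimSpec(seed=0, n_regions=3, poisson=False)
        regions, factors = simulate.gen_edx_counts(spec)
        planted = dict(spec.composition)
        for r in regions:
            comp = edx.relative_atomic_percent(r, factors)
            for el, p in planted.items():
                assert comp.percents[el] == pytest.approx(p, rel=1e-12)

    def test_poisson_mode_recovers_composition_within_one_point(self):
        spec = simulate.EDXSimSpec(seed=3, n_regions=50, total_counts=10_000)
        regions, factors = simulate.gen_edx_counts(spec)
        comps = [edx.relative_atomic_percent(r, factors) for r in regions]
        planted = dict(spec.composition)
        for el, p in planted.items():
            mean = np.mean([c.percents[el] for c in comps])
            assert mean == pytest.approx(p, abs=1.0)

    def test_same_seed_identical_counts(self):
        spec = simulate.EDXSimSpec(seed=8)
        r1, _ = simulate.gen_edx_counts(spec)
        r2, _ = simulate.gen_edx_counts(spec)
        assert all(a.counts == b.counts for a, b in zip(r1, r2))

    def test_nonsimplex_composition_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate.EDXSimSpec(composition=(("S", 50.0), ("Fe", 30.0)))

    def test_nonunit_factors_still_round_trip(self):
        spec = simulate.EDXSimSpec(
            seed=0, n_regions=2, poisson=False,
            factors=(("S", 1.0), ("Fe", 2.5), ("Ni", 0.3)),
        )
        regions, factors = simulate.gen_edx_counts(spec)
        comp = edx.relative_atomic_percent(regions[0], factors)
        for el, p in dict(spec.composition).items():
            assert comp.percents[el] == pytest.approx(p, rel=1e-12)


class TestIsotopeCounts:
    def test_expectation_mode_arithmetic(self):
        pat = simulate.gen_isotope_counts(
            simulate.IsotopeSimSpec(total_counts=97_940, expectation=True), NI
        )
        assert pat.counts["58Ni"] == pytest.approx(68_080.0)
        assert pat.counts["60Ni"] == pytest.approx(26_220.0)
        assert pat.counts["62Ni"] == pytest.approx(3_640.0)

    def test_fractions_sum_to_one_for_any_draw(self):
        pat = simulate.gen_isotope_counts(simulate.IsotopeSimSpec(seed=2), NI)
        frac = isotope.relative_isotope_counts(pat, list(pat.counts))
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_same_seed_identical_draw(self):
        spec = simulate.IsotopeSimSpec(seed=9)
        assert simulate.gen_isotope_counts(spec, NI).counts == \
            simulate.gen_isotope_counts(spec, NI).counts


class TestProteomePair:
    def test_zero_mutation_partners_identical(self):
        spec = simulate.ProteomeSimSpec(seed=4, mutation_rate=0.0)
        prot_a, prot_b, _ = simulate.gen_proteome_pair(spec)
        for k in range(spec.n_planted):
            assert prot_a[k].sequence == prot_b[k].sequence

    def test_planted_heme_counts_survive_mutation(self):
        spec = simulate.ProteomeSimSpec(seed=42)
        prot_a, prot_b, truth = simulate.gen_proteome_pair(spec)
        by_id = {r.id: r for r in prot_a + prot_b}
        for row in truth.itertuples():
            assert heme.scan_heme_motifs(by_id[row.id_a]).heme_count == row.heme_count
            assert heme.scan_heme_motifs(by_id[row.id_b]).heme_count == row.heme_count

    def test_planted_short_pentaheme_classifies_as_sphc(self):
        spec = simulate.ProteomeSimSpec(seed=4)
        prot_a, _, truth = simulate.gen_proteome_pair(spec)
        assert truth.loc[0, "cytochrome_class"] == "pentaheme_sPHC"  # 180 residues
        assert truth.loc[1, "cytochrome_class"] == "pentaheme_lPHC"  # 600 residues

    def test_same_seed_identical_proteomes(self):
        spec = simulate.ProteomeSimSpec(seed=17)
        a1, b1, t1 = simulate.gen_proteome_pair(spec)
        a2, b2, t2 = simulate.gen_proteome_pair(spec)
        assert [r.sequence for r in a1 + b1] == [r.sequence for r in a2 + b2]
        assert t1.equals(t2)

    def test_excessive_mutation_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate.ProteomeSimSpec(mutation_rate=0.5)

    def test_impossible_motif_packing_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate.ProteomeSimSpec(
                n_planted=1, heme_counts=(10,), lengths=(50,)
            )


class TestVesicles:
    def test_all_imav_when_fraction_one(self):
        obs = simulate.gen_vesicles(simulate.VesicleSimSpec(seed=1, n=50, imav_fraction=1.0))
        assert all(o.attachment == "IMAV" for o in obs)

    def test_recovery_of_planted_fraction_and_diameter(self):
        obs = simulate.gen_vesicles(simulate.VesicleSimSpec(seed=11, n=500))
        s = morphometry.summarize_vesicles(obs)
        assert s.imav_fraction == pytest.approx(0.9, abs=0.03)
        assert s.imav_diameter_mean == pytest.approx(65.5, abs=0.5)

    def test_same_seed_identical_sample(self):
        spec = simulate.VesicleSimSpec(seed=6, n=30)
        o1 = simulate.gen_vesicles(spec)
        o2 = simulate.gen_vesicles(spec)
        assert [(o.diameter_nm, o.attachment) for o in o1] == \
            [(o.diameter_nm, o.attachment) for o in o2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate.VesicleSimSpec(imav_fraction=1.2)
        with pytest.raises(InvalidInputError):
            simulate.VesicleSimSpec(imav_diameter_std_nm=0.0)
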