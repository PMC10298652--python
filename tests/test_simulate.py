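"""Meiosis, pedigree advance, genotyping noise and phenotype simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from il_toolkit.model import GenomeMap, Marker, MarkerPanel, ValidationError
from il_toolkit.simulate import (
    DONOR,
    RECURRENT,
    Diplotype,
    QTLEffect,
    TraitArchitecture,
    TraitModel,
    TrialDesign,
    advance_generation,
    donor_fraction,
    genotype_population,
    heterozygous_fraction,
    simulate_gamete,
    simulate_phenotypes,
    true_segments,
)

from conftest import make_panel


class TestGamete:
    def test_zero_cm_chromosome_has_no_crossovers(self, rng):
        genome = GenomeMap.from_lists([("c1", 1_000_000, 0.0)])
        parent = Diplotype.f1(genome)
        for _ in range(20):
            g = simulate_gamete(parent, genome, rng)
            assert len(g["c1"].ends) == 1  # a single parental tract

    def test_homozygous_recurrent_parent_gives_recurrent_gamete(self, rng):
        genome = GenomeMap.from_lists([("c1", 1_000_000, 300.0)])
        parent = Diplotype.fully_recurrent(genome)
        for _ in range(20):
            g = simulate_gamete(parent, genome, rng)
            assert set(g["c1"].ancestry.tolist()) == {RECURRENT}

    def test_requires_explicit_rng(self, single_chrom_genome):
        parent = Diplotype.f1(single_chrom_genome)
        with pytest.raises(TypeError, match="Generator"):
            simulate_gamete(parent, single_chrom_genome, None)

    def test_mean_crossover_count_matches_poisson(self, rng):
        # On an F1 parent every crossover produces an ancestry switch, so
        # tract count - 1 counts crossovers; 100 cM => Poisson(1).
        genome = GenomeMap.from_lists([("c1", 10_000_000, 100.0)])
        parent = Diplotype.f1(genome)
        n = 10_000
        counts = np.array(
            [len(simulate_gamete(parent, genome, rng)["c1"].ends) - 1
             for _ in range(n)]
        )
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_gamete_mosaics_are_valid(self, toy_genome, rng):
        parent = Diplotype.f1(toy_genome)
        for _ in range(50):
            g = simulate_gamete(parent, toy_genome, rng)
            for name, hap in g.items():
                hap.validate()
                assert hap.length == toy_genome[name].length_bp


class TestAdvanceGeneration:
    def test_backcross_of_f1_expected_donor_quarter(self, toy_genome, rng):
        pop = advance_generation(
            [Diplotype.f1(toy_genome)], "backcross_to_recurrent", 400,
            toy_genome, rng,
        )
        fracs = np.array([donor_fraction(d, toy_genome) for d in pop])
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.25) < 3 * se

    def test_empty_population_rejected(self, toy_genome, rng):
        with pytest.raises(ValidationError, match="empty"):
            advance_generation([], "self", 5, toy_genome, rng)

    def test_offspring_are_valid_diplotypes(self, toy_genome, rng):
        pop = [Diplotype.f1(toy_genome)]
        for cross in ("backcross_to_recurrent", "self", "self"):
            pop = advance_generation(pop, cross, 10, toy_genome, rng)
            for d in pop:
                d.validate(toy_genome)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        lengths=st.lists(
            st.tuples(st.integers(1_000_000, 8_000_000),
                      st.floats(0.0, 150.0)),
            min_size=1, max_size=3,
        ),
        t=st.integers(1, 3),
    )
    def test_donor_decay_expectation_on_arbitrary_maps(self, lengths, t):
        # E[donor fraction] after t unselected backcrosses = (1/2)^(t+1),
        # for any genome map.
        genome = GenomeMap.from_lists(
            [(f"c{i}", bp, cm) for i, (bp, cm) in enumerate(lengths)]
        )
        rng = np.random.default_rng(42)
        n = 300
        fracs = []
        for _ in range(n):
            pop = [Diplotype.f1(genome)]
            for _ in range(t):
                pop = advance_generation(
                    pop, "backcross_to_recurrent", 1, genome, rng
                )
            fracs.append(donor_fraction(pop[0], genome))
        fracs = np.array(fracs)
        expected = 0.5 ** (t + 1)
        se = max(fracs.std(ddof=1) / np.sqrt(n), 1e-9)
        assert abs(fracs.mean() - expected) < 4 * se


class TestGenotyping:
    def test_noise_free_matches_truth(self, toy_genome, rng):
        pop = advance_generation(
            [Diplotype.f1(toy_genome)], "self", 5, toy_genome, rng
        )
        panel = make_panel(toy_genome, 500_000)
        m = genotype_population(pop, panel)
        for i, dip in enumerate(pop):
            row = m.calls.iloc[i]
            for marker in panel.markers:
                h1, h2 = dip.haplotypes[marker.chromosome]
                d = h1.ancestry_at(marker.position_bp) + h2.ancestry_at(
                    marker.position_bp
                )
                assert row[marker.id] == {0: "A", 1: "H", 2: "B"}[d]

    def test_missing_rate_one_gives_all_na(self, toy_genome, toy_panel, rng):
        m = genotype_population(
            [Diplotype.f1(toy_genome)], toy_panel, missing_rate=1.0, rng=rng
        )
        assert m.calls.isna().all().all()

    def test_observed_missingness_binomial(self, single_chrom_genome, rng):
        panel = make_panel(single_chrom_genome, 10_000)  # 1000 markers
        pop = [Diplotype.f1(single_chrom_genome)] * 100  # 1e5 calls
        m = genotype_population(pop, panel, missing_rate=0.02, rng=rng)
        n_calls = m.calls.size
        frac = m.calls.isna().to_numpy().mean()
        se = np.sqrt(0.02 * 0.98 / n_calls)
        assert abs(frac - 0.02) < 3 * se

    def test_marker_beyond_chromosome_rejected(self, single_chrom_genome, rng):
        panel = MarkerPanel((Marker("m", "chr01", 10_000_001),))
        with pytest.raises(ValidationError, match="outside"):
            genotype_population([Diplotype.f1(single_chrom_genome)], panel)


def _arch(qtls=(), cv=0.0, **kw):
    means = {"Alcasser": 2500.0, "Meliana": 2600.0}
    return TraitArchitecture(
        {"FW": TraitModel.from_cv(means, cv)}, tuple(qtls), **kw
    )


def _design(**kw):
    return TrialDesign(locations=("Alcasser", "Meliana"), **kw)


def _il_with_segment(toy_genome):
    from il_toolkit.model import ILGenotype, IntrogressionSegment, Zygosity

    return {
        "IL01": ILGenotype(
            "IL01",
            (IntrogressionSegment("chr01", 1_000_000, 3_000_000,
                                  Zygosity.HOM_DONOR),),
        )
    }


class TestPhenotypeSimulation:
    def test_zero_noise_zero_effects_equals_location_mean(self, toy_genome, rng):
        pheno = simulate_phenotypes(_il_with_segment(toy_genome), _arch(),
                                    _design(), rng)
        for loc, mu in [("Alcasser", 2500.0), ("Meliana", 2600.0)]:
            vals = pheno[(pheno.location == loc) & (pheno.trait == "FW")]["value"]
            assert np.allclose(vals, mu)

    def test_multiplicative_percent_effect(self, toy_genome, rng):
        qtl = QTLEffect("FW", "chr01", 2_000_000, 2_500_000, -50.0)
        pheno = simulate_phenotypes(
            _il_with_segment(toy_genome), _arch([qtl]), _design(), rng
        )
        il = pheno[(pheno.line == "IL01") & (pheno.trait == "FW")]
        ps = pheno[(pheno.line == "PS") & (pheno.trait == "FW")]
        for loc, mu in [("Alcasser", 2500.0), ("Meliana", 2600.0)]:
            assert np.allclose(il[il.location == loc]["value"], 0.5 * mu)
            assert np.allclose(ps[ps.location == loc]["value"], mu)

    def test_non_overlapping_qtl_not_expressed(self, toy_genome, rng):
        qtl = QTLEffect("FW", "chr02", 1, 500_000, -50.0)
        pheno = simulate_phenotypes(
            _il_with_segment(toy_genome), _arch([qtl]), _design(), rng
        )
        il = pheno[(pheno.line == "IL01") & (pheno.trait == "FW")]
        assert np.allclose(
            il[il.location == "Alcasser"]["value"], 2500.0
        )

    def test_control_mean_clt(self, toy_genome, rng):
        design = TrialDesign(
            locations=("Alcasser",), n_blocks=50, control_reps_per_block=20
        )
        pheno = simulate_phenotypes(
            _il_with_segment(toy_genome), _arch(cv=0.15), design, rng
        )
        ps = pheno[(pheno.line == "PS") & (pheno.trait == "FW")]["value"]
        se = ps.std(ddof=1) / np.sqrt(len(ps))
        assert len(ps) == 1000
        assert abs(ps.mean() - 2500.0) < 3 * se

    def test_fs_is_derived_ratio_per_fruit(self, toy_genome, rng):
        arch = TraitArchitecture(
            {
                "FL": TraitModel.from_cv({"Alcasser": 215.0}, 0.05),
                "FD": TraitModel.from_cv({"Alcasser": 155.0}, 0.05),
            }
        )
        design = TrialDesign(locations=("Alcasser",))
        pheno = simulate_phenotypes(_il_with_segment(toy_genome), arch, design, rng)
        wide = pheno.pivot_table(
            index=["block", "line", "replicate"], columns="trait", values="value"
        )
        assert np.allclose(wide["FS"], wide["FL"] / wide["FD"])

    def test_fs_cannot_be_simulated_directly(self):
        with pytest.raises(ValidationError, match="derived"):
            TraitArchitecture({"FS": TraitModel.from_cv({"A": 1.4}, 0.1)})

    def test_reproducibility_same_seed(self, toy_genome):
        a = simulate_phenotypes(
            _il_with_segment(toy_genome), _arch(cv=0.1, block_sd_frac=0.02),
            _design(), np.random.default_rng(99),
        )
        b = simulate_phenotypes(
            _il_with_segment(toy_genome), _arch(cv=0.1, block_sd_frac=0.02),
            _design(), np.random.default_rng(99),
        )
        pd.testing.assert_frame_equal(a, b)


class TestTrueSegments:
    def test_f1_truth_is_fully_heterozygous(self, toy_genome):
        segs = true_segments(Diplotype.f1(toy_genome), toy_genome)
        assert len(segs) == len(toy_genome)
        for s, chrom in zip(segs, toy_genome.chromosomes):
            assert (s.start, s.end) == (1, chrom.length_bp)
            assert s.zygosity.value == "heterozygous"

    def test_truth_segments_cover_donor_dosage(self, toy_genome, rng):
        pop = [Diplotype.f1(toy_genome)]
        for cross in ("backcross_to_recurrent", "self"):
            pop = advance_generation(pop, cross, 5, toy_genome, rng)
        from il_toolkit.model import Zygosity

        for dip in pop:
            segs = true_segments(dip, toy_genome)
            dosage = sum(
                s.length * (2 if s.zygosity is Zygosity.HOM_DONOR else 1)
                for s in segs
            )
            expected = donor_fraction(dip, toy_genome) * 2 * toy_genome.total_length_bp
            assert dosage == pytest.approx(expected)
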