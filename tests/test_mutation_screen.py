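"""Mutation screen tests: consensus, depth rules, classification, density."""

import numpy as np
import pytest
from scipy import stats

from irradgbs import mutation_screen as ms
from irradgbs.synthetic_gbs import SBS_CATEGORIES
from irradgbs.variant_io import GenotypeMatrix, VariantRecord

CONTROLS = ["c1", "c2", "c3", "c4"]
SITE = ("chr01", 100, "G", "A")


def matrix_with(records):
    m = GenotypeMatrix(CONTROLS + ["mut"])
    for rec in records:
        m.add(rec)
    return m


def rec(sample, depth, ad, ref="G", alt="A", pos=100):
    return VariantRecord("chr01", pos, ref, alt, sample, depth, ad)


class TestControlConsensus:
    def test_unanimous_controls_give_consensus(self):
        m = matrix_with([rec(c, 8, (8, 0)) for c in CONTROLS])
        assert ms.control_consensus(m, CONTROLS) == {SITE: "G"}

    def test_disagreeing_control_blocks_site(self):
        records = [rec(c, 8, (8, 0)) for c in CONTROLS[:3]]
        records.append(rec("c4", 8, (0, 8)))
        m = matrix_with(records)
        assert ms.control_consensus(m, CONTROLS) == {}

    def test_shallow_control_blocks_site(self):
        records = [rec(c, 8, (8, 0)) for c in CONTROLS[:3]]
        records.append(rec("c4", 3, (3, 0)))
        m = matrix_with(records)
        assert ms.control_consensus(m, CONTROLS) == {}

    def test_uncovered_control_blocks_site(self):
        m = matrix_with([rec(c, 8, (8, 0)) for c in CONTROLS[:3]])
        assert ms.control_consensus(m, CONTROLS) == {}

    def test_impure_control_blocks_site(self):
        # a control showing the other allele at 30% is not clearly homozygous
        records = [rec(c, 10, (10, 0)) for c in CONTROLS[:3]]
        records.append(rec("c4", 10, (7, 3)))
        m = matrix_with(records)
        assert ms.control_consensus(m, CONTROLS) == {}

    def test_no_controls_is_configuration_error(self):
        with pytest.raises(ValueError):
            ms.control_consensus(matrix_with([]), [])


class TestScreenMutations:
    def base_records(self):
        return [rec(c, 8, (8, 0)) for c in CONTROLS]

    def test_heterozygous_variant_at_depth_called(self):
        m = matrix_with(self.base_records() + [rec("mut", 7, (3, 4))])
        calls = ms.screen_mutations(m, CONTROLS, "mut")
        assert len(calls) == 1
        assert calls[0].mtype == "SBS" and calls[0].alt == "A"

    def test_depth_below_five_not_called(self):
        m = matrix_with(self.base_records() + [rec("mut", 4, (2, 2))])
        assert ms.screen_mutations(m, CONTROLS, "mut") == []

    def test_low_allele_fraction_treated_as_noise(self):
        m = matrix_with(self.base_records() + [rec("mut", 20, (17, 3))])
        assert ms.screen_mutations(m, CONTROLS, "mut") == []

    def test_net_one_insertion_called_net_three_excluded(self):
        recs = []
        for c in CONTROLS:
            recs.append(rec(c, 8, (8, 0), ref="GA", alt="GAT", pos=200))
            recs.append(rec(c, 8, (8, 0), ref="GA", alt="GATTT", pos=300))
        recs.append(rec("mut", 10, (5, 5), ref="GA", alt="GAT", pos=200))
        recs.append(rec("mut", 10, (5, 5), ref="GA", alt="GATTT", pos=300))
        m = matrix_with(recs)
        calls = ms.screen_mutations(m, CONTROLS, "mut")
        assert len(calls) == 1
        assert calls[0].mtype == "INS" and calls[0].indel_len == 1
        assert calls[0].position == 200

    def test_absent_mutant_sample_is_lookup_error(self):
        m = matrix_with(self.base_records())
        with pytest.raises(KeyError):
            ms.screen_mutations(m, CONTROLS, "nobody")

    def test_raising_min_depth_never_adds_calls(self, clean_sim):
        from irradgbs.mutation_screen import screen_mutations

        controls = [f"control_{i}" for i in range(1, 5)]
        mutant = "pistil_60Gy_rep1"
        previous = None
        for depth in (1, 3, 5, 8, 12, 20):
            n = len(
                screen_mutations(clean_sim.matrix, controls, mutant,
                                 min_depth=depth)
            )
            if previous is not None:
                assert n <= previous
            previous = n


class TestScreenRecovery:
    def test_clean_data_recovers_truth_exactly(self, clean_sim):
        calls, _ = ms.screen_panel(
            clean_sim.matrix, clean_sim.manifest, clean_sim.genome.mapped_length
        )
        called = {(c.sample, c.chromosome, c.position, c.ref, c.alt)
                  for c in calls}
        truth = {(m.sample, m.chromosome, m.position, m.ref, m.alt)
                 for m in clean_sim.truth.injected_mutations}
        assert called == truth


class TestClassifySbs:
    def test_twelve_pairs_collapse_into_six_categories_of_two(self):
        seen = {}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                cat, _ = ms.classify_sbs(ref, alt)
                seen.setdefault(cat, []).append((ref, alt))
        assert set(seen) == set(SBS_CATEGORIES)
        assert all(len(v) == 2 for v in seen.values())

    def test_strand_complement_gives_same_category(self):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert ms.classify_sbs(ref, alt) == ms.classify_sbs(
                    comp[ref], comp[alt]
                )

    @pytest.mark.parametrize(
        "ref,alt,category,titv",
        [
            ("G", "A", "G/C>A/T", "transition"),
            ("A", "G", "A/T>G/C", "transition"),
            ("T", "C", "A/T>G/C", "transition"),
            ("G", "T", "G/C>T/A", "transversion"),
        ],
    )
    def test_known_classifications(self, ref, alt, category, titv):
        assert ms.classify_sbs(ref, alt) == (category, titv)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            ms.classify_sbs("N", "A")


class TestDensity:
    def test_zero_mutations_zero_density(self):
        assert ms.mutation_density(0, 1_000_000).density == 0.0

    def test_per_10mb_arithmetic(self):
        est = ms.mutation_density(17, 11_449_437)
        assert round(est.density, 2) == 14.85

    def test_unit_case(self):
        assert ms.mutation_density(10, 10_000_000).density == 10.0

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            ms.mutation_density(1, 0)

    def test_density_scales_linearly_with_injection(self):
        from irradgbs import synthetic_gbs as sg

        base = dict(
            n_chromosomes=2, chrom_length=3_000_000, n_regions=6_000,
            region_length_mean=144, snp_rate=0.0, depth_mean=30,
            depth_dispersion=20, genotype_error_rate=0.0, n_progeny=0,
            n_controls=4, n_mutants_per_group=30, mutant_groups=("g",),
        )
        means, variances, n_lines = [], [], []
        for density in (15.0, 30.0):
            config = sg.SimConfig(mutation_density=density, seed=21, **base)
            result = sg.simulate_dataset(config)
            _, table = ms.screen_panel(
                result.matrix, result.manifest, result.genome.mapped_length
            )
            means.append(table["density_per_10mb"].mean())
            variances.append(table["density_per_10mb"].var(ddof=1))
            n_lines.append(len(table))
        # doubling the injected density doubles the estimate in expectation
        se_diff = np.sqrt(
            variances[1] / n_lines[1] + 4 * variances[0] / n_lines[0]
        )
        assert abs(means[1] - 2 * means[0]) <= 3 * se_diff


class TestGenerationCorrection:
    def test_reference_back_correction(self):
        assert ms.correct_generation_density(1.25) == pytest.approx(1.5)

    def test_no_heterozygotes_means_no_correction(self):
        assert ms.correct_generation_density(3.7, het_fraction=0.0) == 3.7

    def test_closed_form(self):
        assert ms.correct_generation_density(
            1.0, het_fraction=1.0, loss=0.25
        ) == pytest.approx(4 / 3)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ms.correct_generation_density(1.0, het_fraction=1.5)
        with pytest.raises(ValueError):
            ms.correct_generation_density(1.0, loss=1.0)


def _sbs_call(sample, category, i):
    ref = {"A/T>G/C": "A", "G/C>A/T": "G", "A/T>T/A": "A",
           "A/T>C/G": "A", "G/C>T/A": "G", "G/C>C/G": "G"}[category]
    alt = {"A/T>G/C": "G", "G/C>A/T": "A", "A/T>T/A": "T",
           "A/T>C/G": "C", "G/C>T/A": "T", "G/C>C/G": "C"}[category]
    titv = "transition" if category in ms.TRANSITION_CATEGORIES else "transversion"
    return ms.MutationCall(sample, "chr01", i + 1, ref, alt, "SBS", 0,
                           category, titv)


class TestSpectrumTable:
    def test_single_category_has_proportion_one(self):
        calls = [_sbs_call("m", "G/C>A/T", i) for i in range(10)]
        table = ms.spectrum_table({"g": calls})
        row = table.set_index("category").loc["G/C>A/T"]
        assert row["proportion"] == 1.0
        transitions = table[table.ti_tv == "transition"]["proportion"].sum()
        assert transitions == 1.0

    def test_uniform_categories_give_one_third_transitions(self):
        calls = [
            _sbs_call("m", cat, i)
            for i, cat in enumerate(SBS_CATEGORIES * 5)
        ]
        table = ms.spectrum_table({"g": calls})
        transitions = table[table.ti_tv == "transition"]["proportion"].sum()
        assert transitions == pytest.approx(1 / 3)

    def test_zero_sbs_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            table = ms.spectrum_table(
                {"empty": [], "ok": [_sbs_call("m", "A/T>G/C", 0)]}
            )
        assert set(table["group"]) == {"ok"}

    def test_multinomial_proportions_within_ci(self):
        p = np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.1])
        rng = np.random.default_rng(17)
        n = 5000
        draws = rng.choice(len(SBS_CATEGORIES), size=n, p=p)
        calls = [
            _sbs_call("m", SBS_CATEGORIES[k], i) for i, k in enumerate(draws)
        ]
        table = ms.spectrum_table({"g": calls}).set_index("category")
        for k, cat in enumerate(SBS_CATEGORIES):
            lo, hi = stats.binom.interval(0.99, n, p[k])
            assert lo / n <= table.loc[cat, "proportion"] <= hi / n


class TestAnnotateCalls:
    def test_contexts_partition_calls(self, clean_sim):
        calls, _ = ms.screen_panel(
            clean_sim.matrix, clean_sim.manifest, clean_sim.genome.mapped_length
        )
        annotated = ms.annotate_calls(calls, clean_sim.genome.annotation_index())
        contexts = [c.context for c in annotated]
        assert len(annotated) == len(calls)
        assert set(contexts) <= {"exon", "intron", "intergenic"}

    def test_unknown_chromosome_is_lookup_error(self, clean_sim):
        index = clean_sim.genome.annotation_index()
        bad = [ms.MutationCall("m", "chrXX", 5, "A", "G", "SBS", 0,
                               "A/T>G/C", "transition")]
        with pytest.raises(KeyError, match="chrXX"):
            ms.annotate_calls(bad, index)
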