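"""The synthetic-read generator: junction-mutation model, both library types,
and the synthetic genome."""

import numpy as np
import pytest

from oracles import rc
from replaceseq.design import enumerate_outcomes, outcome_by_class
from replaceseq.simulate import (
    OutcomeMixture,
    default_anchor,
    mutate_junction,
    plant_offtarget_loci,
    simulate_donor_anchored,
    simulate_genome,
    simulate_linamp,
    simulate_longread,
    staggered_insertion,
)


class TestStaggeredInsertion:
    def test_duplicates_protospacer_positions(self, design):
        g = design.guide_left
        assert staggered_insertion(g, 1) == g.protospacer[16:17]
        assert staggered_insertion(g, 2) == g.protospacer[15:17]

    def test_rejects_other_lengths(self, design):
        with pytest.raises(ValueError):
            staggered_insertion(design.guide_left, 3)


class TestMutateJunction:
    def test_perfect_mixture_is_identity(self, design):
        mix = OutcomeMixture(weights={"replacement_fwd": 1.0}, p_perfect=1.0,
                             p_stagger1=0.0, p_stagger2=0.0)
        allele = outcome_by_class(design)["replacement_fwd"]
        for ji in (0, 1):
            seq, edit = mutate_junction(allele, ji, mix, rng_seed=5)
            assert seq == allele.sequence
            assert edit.type == "none"

    def test_stagger_only_at_pam_pam_junctions(self, design):
        # replacement_fwd: junction 0 joins two protospacer sides, junction 1
        # two PAM sides; insertions may only ever appear at junction 1
        mix = OutcomeMixture(weights={"replacement_fwd": 1.0}, p_perfect=0.0,
                             p_stagger1=0.5, p_stagger2=0.5)
        allele = outcome_by_class(design)["replacement_fwd"]
        proto = design.guide_left.protospacer
        for seed in range(200):
            seq0, e0 = mutate_junction(allele, 0, mix, rng_seed=seed)
            assert e0.type == "none" and seq0 == allele.sequence
            seq1, e1 = mutate_junction(allele, 1, mix, rng_seed=seed)
            assert e1.type == "insertion"
            assert e1.inserted in (proto[16:17], proto[15:17])
            assert len(seq1) == len(allele.sequence) + e1.size

    def test_deletion_sizes_follow_geometric_mean(self, design):
        p = 0.3
        mix = OutcomeMixture(weights={"replacement_fwd": 1.0}, p_perfect=0.0,
                             p_stagger1=0.0, p_stagger2=0.0, del_geom_p=p,
                             p_large_resection=0.0)
        allele = outcome_by_class(design)["replacement_fwd"]
        sizes = []
        for seed in range(10_000):
            _, e = mutate_junction(allele, 0, mix, rng_seed=seed)
            assert e.type == "deletion" and e.size >= 1
            sizes.append(e.size)
        mean, exp_mean = np.mean(sizes), 1.0 / p
        se = np.sqrt((1 - p) / p**2 / len(sizes))
        assert abs(mean - exp_mean) < 3 * se

    def test_invalid_junction_index(self, design):
        allele = outcome_by_class(design)["deletion"]
        mix = OutcomeMixture(weights={"deletion": 1.0})
        with pytest.raises(IndexError):
            mutate_junction(allele, 5, mix, rng_seed=0)


class TestMixtureValidation:
    def test_weights_normalized(self):
        m = OutcomeMixture(weights={"original": 2.0, "deletion": 2.0})
        assert m.weights == {"original": 0.5, "deletion": 0.5}

    def test_rejects_unknown_class(self):
        with pytest.raises(ValueError):
            OutcomeMixture(weights={"weird": 1.0})

    def test_rejects_excess_probability(self):
        with pytest.raises(ValueError):
            OutcomeMixture(p_perfect=0.8, p_stagger1=0.2, p_stagger2=0.1)

    def test_yaml_roundtrip(self, tmp_path, demo_mixture):
        p = tmp_path / "mix.yaml"
        demo_mixture.to_yaml(p)
        back = OutcomeMixture.from_yaml(p)
        assert back == demo_mixture


class TestSimulateLongread:
    def test_all_original_reads_equal_unedited_amplicon(self, design):
        mix = OutcomeMixture(weights={"original": 1.0}, p_perfect=1.0,
                             p_stagger1=0.0, p_stagger2=0.0)
        reads, truth = simulate_longread(design, mix, 50, seed=9)
        amp = design.locus_seq[30 : len(design.locus_seq) - 30]
        for r in reads:
            assert r.sequence in (amp, rc(amp))
        assert set(truth.klass) == {"original"}

    def test_mutation_free_reads_are_substrings_of_enumerated_alleles(
        self, design, demo_mixture
    ):
        mix = OutcomeMixture(weights=dict(demo_mixture.weights), p_perfect=1.0,
                             p_stagger1=0.0, p_stagger2=0.0)
        reads, _ = simulate_longread(design, mix, 200, seed=2)
        alleles = [al.sequence for al in enumerate_outcomes(design)]
        for r in reads:
            fwd = r.sequence
            assert any(fwd in s or rc(fwd) in s for s in alleles)

    def test_truth_table_complete_and_unique(self, design, demo_mixture):
        reads, truth = simulate_longread(design, demo_mixture, 300, seed=3)
        assert sorted(truth.read_id) == sorted(r.id for r in reads)
        assert truth.read_id.is_unique

    def test_class_counts_within_3_binomial_se(self, design):
        weights = {"original": 0.2, "replacement_fwd": 0.4,
                   "replacement_rev": 0.1, "deletion": 0.2,
                   "insertion_up_fwd": 0.1}
        mix = OutcomeMixture(weights=weights)
        n = 5000
        _, truth = simulate_longread(design, mix, n, seed=42,
                                     length_bias_alpha=0.0)
        counts = truth.klass.value_counts()
        for k, w in weights.items():
            se = np.sqrt(w * (1 - w) / n)
            assert abs(counts.get(k, 0) / n - w) < 3 * se, k

    def test_length_bias_overrepresents_short_amplicons(self, design):
        # deletion amplicon is much shorter than the insertion amplicon; a
        # positive alpha must pull the realized fraction above the weight
        weights = {"deletion": 0.5, "insertion_up_fwd": 0.5}
        alpha = 0.004
        out = outcome_by_class(design)
        len_del = len(out["deletion"].sequence) - 60
        len_ins = len(out["insertion_up_fwd"].sequence) - 60
        expected = (0.5 * np.exp(-alpha * len_del)) / (
            0.5 * np.exp(-alpha * len_del) + 0.5 * np.exp(-alpha * len_ins)
        )
        n = 4000
        _, truth = simulate_longread(
            design, OutcomeMixture(weights=weights), n, seed=8,
            length_bias_alpha=alpha,
        )
        frac = (truth.klass == "deletion").mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert frac > 0.5
        assert abs(frac - expected) < 3 * se

    def test_primers_must_flank_cuts(self, design, demo_mixture):
        with pytest.raises(ValueError):
            simulate_longread(design, demo_mixture, 10,
                              primer_left_offset=design.cut_left + 1)

    def test_deterministic_under_seed(self, design, demo_mixture):
        r1, t1 = simulate_longread(design, demo_mixture, 100, seed=77)
        r2, t2 = simulate_longread(design, demo_mixture, 100, seed=77)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)


class TestSimulateLinamp:
    def test_reads_start_at_anchor_and_carry_umis(self, design, demo_mixture):
        reads, truth = simulate_linamp(design, demo_mixture, 100, seed=4)
        anchor = default_anchor(design)
        for r in reads:
            assert r.sequence.startswith(anchor)
            assert r.umi is not None and len(r.umi) == 10
        assert truth.read_id.is_unique

    def test_umi_collisions_match_birthday_expectation(self, design):
        mix = OutcomeMixture(weights={"original": 1.0})
        n = 10_000
        _, truth = simulate_linamp(design, mix, n, seed=13, umi_len=10)
        distinct = truth.umi.nunique()
        U = 4**10
        expected_distinct = U * (1 - (1 - 1 / U) ** n)
        n_collisions = n - expected_distinct
        tol = 3 * np.sqrt(n_collisions) + 1
        assert abs(distinct - expected_distinct) < tol

    def test_molecule_reads_are_identical(self, design, demo_mixture):
        reads, truth = simulate_linamp(design, demo_mixture, 400, seed=6,
                                       mean_reads_per_molecule=3.0)
        by_mol = {}
        for r, mol in zip(reads, truth.molecule_id):
            by_mol.setdefault(mol, set()).add(r.sequence)
        assert all(len(v) == 1 for v in by_mol.values())
        assert truth.molecule_id.nunique() < len(reads)


class TestSyntheticGenome:
    def test_deterministic_and_sized(self):
        g1 = simulate_genome(n_chrom=2, chrom_len=12_000, n_offtarget_sites=40,
                             seed=5)
        g2 = simulate_genome(n_chrom=2, chrom_len=12_000, n_offtarget_sites=40,
                             seed=5)
        assert g1.chromosomes == g2.chromosomes
        assert g1.predicted_offtargets == g2.predicted_offtargets

    def test_predicted_site_count_and_bounds(self, design):
        g = simulate_genome(n_chrom=2, chrom_len=15_000, n_offtarget_sites=293,
                            seed=1, design=design)
        assert len(g.predicted_offtargets) == 293
        for c, p in g.predicted_offtargets:
            assert 0 <= p < len(g.chromosomes[c])
        # embedded locus is recoverable
        assert g.chromosomes[g.locus_chrom][
            g.locus_pos : g.locus_pos + len(design.locus_seq)
        ] == design.locus_seq

    def test_rejects_tiny_chromosomes(self):
        with pytest.raises(ValueError):
            simulate_genome(chrom_len=5000)

    def test_planted_loci_respect_predicted_distance(self, design):
        g = simulate_genome(n_chrom=2, chrom_len=120_000, n_offtarget_sites=8,
                            seed=2, design=design)
        loci = plant_offtarget_loci(g, n_loci=10, min_predicted_distance=6000,
                                    seed=3)
        assert len(loci) == 10
        for c, p, _s in loci:
            dists = [abs(p - sp) for sc, sp in g.predicted_offtargets if sc == c]
            assert not dists or min(dists) > 6000


class TestDonorAnchored:
    def test_category_fractions_and_truth(self, design):
        g = simulate_genome(n_chrom=2, chrom_len=150_000, n_offtarget_sites=10,
                            seed=3, design=design)
        n = 3000
        reads, truth, loci = simulate_donor_anchored(
            design, g, n, p_offtarget=0.11, p_concat=0.34, n_offtarget_loci=6,
            seed=4,
        )
        frac = truth.category.value_counts(normalize=True)
        for cat, p in (("concatemer", 0.34), ("off_target", 0.11),
                       ("on_target", 0.55)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac[cat] - p) < 3 * se, cat
        assert len(loci) == 6
        assert set(truth.read_id) == {r.id for r in reads}

    def test_pure_on_target_flank_is_locus_sequence(self, design):
        g = simulate_genome(n_chrom=2, chrom_len=150_000, n_offtarget_sites=5,
                            seed=3, design=design)
        reads, truth, _ = simulate_donor_anchored(
            design, g, 30, p_offtarget=0.0, p_concat=0.0, seed=9,
        )
        from replaceseq.simulate import donor_primer_and_terminal

        primer, terminal = donor_primer_and_terminal(design)
        downstream = design.locus_seq[design.cut_right :]
        for r in reads:
            assert r.sequence.startswith(primer)
            flank = r.sequence[len(primer) + len(terminal) :]
            assert downstream.startswith(flank[: len(downstream)])
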