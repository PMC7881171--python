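"""Single-primer library quantification: references, assignment, UMI tallies."""

import numpy as np
import pytest

from oracles import cut_and_ligate, rc
from replaceseq.linamp import (
    ReadAssignment,
    assign_and_call,
    build_expected_references,
    outcome_report,
    tally_umis,
)
from replaceseq.simulate import (
    OutcomeMixture,
    ReadRecord,
    default_anchor,
    simulate_linamp,
)


@pytest.fixture(scope="module")
def anchor(design):
    return default_anchor(design)


@pytest.fixture(scope="module")
def refs(design, anchor):
    return build_expected_references(design, anchor)


def _ref(refs, klass):
    return next(r for r in refs if r.klass == klass)


class TestBuildReferences:
    def test_all_begin_with_anchor(self, refs, anchor):
        assert all(r.sequence.startswith(anchor) for r in refs)

    def test_deletion_reference_joins_across_excision(self, design, refs, anchor):
        start = design.locus_seq.find(anchor)
        expected = (design.locus_seq[start : design.cut_left]
                    + design.locus_seq[design.cut_right :])
        got = _ref(refs, "deletion").sequence
        assert expected.startswith(got) or got.startswith(expected)

    def test_replacement_rev_contains_rc_donor_at_cut(self, design, refs, anchor):
        start = design.locus_seq.find(anchor)
        ref = _ref(refs, "replacement_rev").sequence
        offset = design.cut_left - start
        assert ref[offset:].startswith(rc(design.donor_seq)[: len(ref) - offset])

    def test_reference_count_matches_outcome_enumeration(self, design, refs):
        oracle = cut_and_ligate(design.locus_seq, design.cut_left,
                                design.cut_right, design.donor_seq)
        assert {r.klass for r in refs} == set(oracle)

    def test_ambiguous_anchor_rejected(self, design):
        # find a short substring that occurs more than once in the locus
        locus = design.locus_seq
        repeated = next(
            locus[i : i + 6] for i in range(len(locus) - 6)
            if locus.count(locus[i : i + 6]) > 1
        )
        with pytest.raises(ValueError, match="ambiguous"):
            build_expected_references(design, repeated)

    def test_absent_anchor_rejected(self, design):
        with pytest.raises(ValueError, match="not found"):
            build_expected_references(design, "T" * 25)

    def test_anchor_must_be_upstream_of_cut(self, design):
        downstream = design.locus_seq[design.cut_right : design.cut_right + 25]
        with pytest.raises(ValueError):
            build_expected_references(design, downstream)


class TestAssignAndCall:
    def test_perfect_read_assigned_with_clean_junctions(self, refs, anchor):
        read = _ref(refs, "replacement_fwd").sequence[:300]
        [a] = assign_and_call([read], refs, anchor)
        assert a.status == "assigned" and a.klass == "replacement_fwd"
        assert [c.type for c in a.junction_calls] == ["none", "none"]

    def test_read_stopping_before_junction_counts_class_not_junction(
        self, refs, anchor
    ):
        ref = _ref(refs, "replacement_fwd")
        j2 = ref.junctions[1]
        read = ref.sequence[: j2 - 5]  # stops 5 nt before the second junction
        [a] = assign_and_call([read], refs, anchor)
        assert a.status == "assigned" and a.klass == "replacement_fwd"
        assert a.junction_calls[0].type == "none"
        assert a.junction_calls[1].type == "not_covered"

    def test_off_primer_reads_discarded(self, refs, anchor):
        body = _ref(refs, "original").sequence[len(anchor):300]
        corrupt = list(anchor)
        for i in (2, 5, 9):  # three mismatches: over the two-mismatch budget
            corrupt[i] = "A" if corrupt[i] != "A" else "C"
        bad = "".join(corrupt) + body
        too_short = anchor[:10]
        out = assign_and_call([bad, too_short], refs, anchor)
        assert [a.status for a in out] == ["off_primer", "off_primer"]

    def test_two_primer_mismatches_tolerated(self, refs, anchor):
        seq = list(_ref(refs, "original").sequence[:300])
        seq[3] = "A" if seq[3] != "A" else "C"
        seq[7] = "A" if seq[7] != "A" else "C"
        [a] = assign_and_call(["".join(seq)], refs, anchor)
        assert a.status == "assigned" and a.klass == "original"

    def test_status_partition(self, design, refs, anchor, demo_mixture):
        reads, _ = simulate_linamp(design, demo_mixture, 200, seed=31)
        out = assign_and_call(reads, refs, anchor)
        assert len(out) == 200
        statuses = {"assigned", "unclassified", "off_primer"}
        assert all(a.status in statuses for a in out)

    def test_class_fractions_recover_truth(self, design, refs, anchor,
                                           demo_mixture):
        n = 1200
        reads, truth = simulate_linamp(design, demo_mixture, n, seed=32)
        out = assign_and_call(reads, refs, anchor)
        assigned = [a for a in out if a.status == "assigned"]
        for k, w in demo_mixture.weights.items():
            frac = sum(a.klass == k for a in assigned) / len(assigned)
            se = np.sqrt(w * (1 - w) / n)
            assert abs(frac - w) < 3 * se, k


def _asg(read_id, klass, umi):
    return ReadAssignment(read_id, "assigned", klass=klass, umi=umi,
                          junction_calls=[])


class TestTallyUmis:
    def test_distinct_umis_counted_once(self):
        asg = [_asg(f"r{i}", "replacement_fwd", f"UMI{i % 4}") for i in range(10)]
        table = tally_umis(asg)
        assert table.counts == {"replacement_fwd": 4}
        assert table.counted_by == "umi"

    def test_majority_resolves_conflicting_umi(self):
        asg = [_asg("r1", "replacement_fwd", "U"),
               _asg("r2", "replacement_fwd", "U"),
               _asg("r3", "replacement_fwd", "U"),
               _asg("r4", "deletion", "U")]
        table = tally_umis(asg)
        assert table.counts == {"replacement_fwd": 1}

    def test_tied_umi_discarded(self):
        asg = [_asg("r1", "replacement_fwd", "U"), _asg("r2", "deletion", "U")]
        table = tally_umis(asg)
        assert table.counts == {} and table.n_discarded_umis == 1

    def test_no_umis_falls_back_to_read_counting(self, caplog):
        asg = [_asg(f"r{i}", "deletion", None) for i in range(5)]
        with caplog.at_level("WARNING"):
            table = tally_umis(asg)
        assert table.counted_by == "read"
        assert table.counts == {"deletion": 5}
        assert any("falling back" in r.message for r in caplog.records)

    def test_molecule_count_recovered_within_2_percent(self, design,
                                                       demo_mixture):
        # ~2000 molecules at a mean of 5 reads per molecule
        reads, truth = simulate_linamp(
            design, demo_mixture, 10_000, seed=33, mean_reads_per_molecule=5.0
        )
        anchor = default_anchor(design)
        refs = build_expected_references(design, anchor)
        table = tally_umis(assign_and_call(reads, refs, anchor))
        true_molecules = truth.molecule_id.nunique()
        assert abs(table.n_molecules - true_molecules) / true_molecules < 0.02


class TestInvariances:
    def test_order_and_umi_relabeling_invariance(self, design, refs, anchor,
                                                 demo_mixture):
        reads, _ = simulate_linamp(design, demo_mixture, 250, seed=34,
                                   mean_reads_per_molecule=2.0)
        base = tally_umis(assign_and_call(reads, refs, anchor))

        shuffled = list(reads)[::-1]
        relabel = {u: f"X{i:04d}" for i, u in
                   enumerate(sorted({r.umi for r in reads}))}
        renamed = [
            ReadRecord(id=r.id, sequence=r.sequence, umi=relabel[r.umi])
            for r in shuffled
        ]
        again = tally_umis(assign_and_call(renamed, refs, anchor))
        assert again.counts == base.counts

    def test_umiless_fractions_equal_read_level(self, design, refs, anchor,
                                                demo_mixture):
        reads, _ = simulate_linamp(design, demo_mixture, 300, seed=35)
        stripped = [ReadRecord(id=r.id, sequence=r.sequence, umi=None)
                    for r in reads]
        out = assign_and_call(stripped, refs, anchor)
        table = tally_umis(out)
        assigned = [a for a in out if a.status == "assigned"]
        read_counts = {}
        for a in assigned:
            read_counts[a.klass] = read_counts.get(a.klass, 0) + 1
        assert table.counts == read_counts


class TestOutcomeReport:
    def test_all_original_reports_fraction_one(self, design, refs, anchor):
        mix = OutcomeMixture(weights={"original": 1.0})
        reads, _ = simulate_linamp(design, mix, 60, seed=36)
        rep = outcome_report(tally_umis(assign_and_call(reads, refs, anchor)))
        assert rep["class_fractions"] == {"original": 1.0}
        assert rep["orientation_ratios"] == {}

    def test_orientation_ratio_recovered(self, design, refs, anchor):
        mix = OutcomeMixture(weights={"replacement_fwd": 5 / 6,
                                      "replacement_rev": 1 / 6})
        n = 900
        reads, _ = simulate_linamp(design, mix, n, seed=37)
        rep = outcome_report(tally_umis(assign_and_call(reads, refs, anchor)))
        ratio = rep["orientation_ratios"]["replacement"]
        se = np.sqrt((5 / 6) * (1 / 6) / n)
        assert abs(ratio["fwd_fraction"] - 5 / 6) < 3 * se

    def test_indel_free_fraction_reported(self, design, refs, anchor):
        mix = OutcomeMixture(weights={"replacement_fwd": 1.0}, p_perfect=1.0,
                             p_stagger1=0.0, p_stagger2=0.0)
        reads, _ = simulate_linamp(design, mix, 50, seed=38)
        rep = outcome_report(tally_umis(assign_and_call(reads, refs, anchor)))
        per_j = rep["junction_indel_free"]["replacement_fwd"]
        assert all(j["indel_free_fraction"] == 1.0 for j in per_j)
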