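"""Conservation classes, covariation and pseudoknot-aware stem recovery."""

import numpy as np
import pytest

from telotrace.structure_annotation import (
    CoreMSA,
    annotate_core,
    conservation_classes,
    covariation_test,
    dot_bracket,
    find_stem,
)
from telotrace.synthetic_data import make_tr_core_family


def _msa(rows, template=(0, 1)):
    return CoreMSA([f"s{i}" for i in range(len(rows))], rows, template)


class TestConservationClasses:
    def test_all_same_base_invariant(self):
        msa = _msa(["UU"] * 10, (0, 1))
        assert conservation_classes(msa)[1] == "invariant"

    def test_ninety_percent_exactly_is_not_conserved90(self):
        """The rule is strictly greater than 90%: 9 of 10 rows is exactly
        90% and therefore variable."""
        msa = _msa(["AA"] * 9 + ["GA"], (1, 2))
        assert conservation_classes(msa)[0] == "variable"

    def test_above_ninety_percent_conserved(self):
        msa = _msa(["AA"] * 19 + ["GA"], (1, 2))
        assert conservation_classes(msa)[0] == "conserved90"

    def test_stem_column_with_covariation_classified_covariant(self):
        rows = ["A" + "CC" + "T"] * 6 + ["G" + "CC" + "C"] * 4
        msa = _msa(rows, (1, 3))
        classes = conservation_classes(msa, stems=[[(0, 3)]])
        assert classes[0] == "covariant"
        assert classes[3] == "covariant"


class TestCovariationTest:
    def test_single_pair_type_is_conservation_not_covariation(self):
        msa = _msa(["AT"] * 10)
        assert covariation_test(msa, 0, 1) is False

    def test_two_pair_types_fully_complementary(self):
        msa = _msa(["AT"] * 5 + ["GC"] * 5)
        assert covariation_test(msa, 0, 1) is True

    def test_below_pair_fraction_threshold(self):
        msa = _msa(["AT"] * 8 + ["AA"] * 2)
        assert covariation_test(msa, 0, 1) is False

    def test_gu_counts_as_complementary(self):
        msa = _msa(["GU"] * 5 + ["AU"] * 5)
        assert covariation_test(msa, 0, 1) is True

    def test_column_order_enforced(self):
        with pytest.raises(ValueError):
            covariation_test(_msa(["AT"] * 5), 1, 0)


class TestFindStem:
    def test_planted_stem_with_compensatory_changes(self):
        """A 6-bp stem with 2 covariant pairs is recovered exactly with
        score = 6 pairs + 2 covariation bonuses."""
        arm = "AGCUCG"
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(arm))
        rows = []
        for r in range(10):
            a, b = list(arm), list(rc)
            if r >= 5:  # compensatory change at stem positions 1 and 3
                a[1], b[4] = "C", "G"
                a[3], b[2] = "A", "U"
            rows.append("".join(a) + "AAAA" + "".join(b))
        msa = _msa(rows, (6, 7))
        stem = find_stem(msa, (0, 6), (10, 16))
        assert stem.pairs == [(0, 15), (1, 14), (2, 13), (3, 12), (4, 11), (5, 10)]
        assert stem.score == 8
        assert len(stem.covariant) == 2

    def test_random_alignments_rarely_contain_stems(self):
        found = 0
        rng = np.random.default_rng(0)
        for _ in range(100):
            rows = ["".join("ACGU"[i] for i in rng.integers(0, 4, 30)) for _ in range(10)]
            if find_stem(_msa(rows, (14, 15)), (0, 14), (15, 30)) is not None:
                found += 1
        assert found <= 5

    def test_tie_broken_to_five_prime_block(self):
        # two identical 3-bp stems; the 5'-most must win
        rows = ["GGG" + "AA" + "GGG" + "TT" + "CCC" + "AA" + "CCC"] * 10
        msa = _msa(rows, (8, 9))
        stem = find_stem(msa, (0, 8), (9, 18))
        assert stem.pairs[0][0] == 0


class TestAnnotateCore:
    def test_recovers_planted_family_stems_exactly(self):
        hits = 0
        for seed in range(10):
            msa, truth = make_tr_core_family(n_rows=10, seed=seed)
            ann = annotate_core(msa)
            if all(ann.stems()[k] == truth["stems"][k] for k in ("p1c", "p1_1", "p2", "p3")):
                hits += 1
        assert hits >= 9

    def test_invariant_u_in_j23_detected(self):
        msa, truth = make_tr_core_family(n_rows=10, seed=1)
        ann = annotate_core(msa)
        assert ann.j2_3 == truth["j2_3"]
        assert ann.invariant_U_in_J23

    def test_identical_sequences_have_no_covariant_columns(self):
        msa, _ = make_tr_core_family(n_rows=8, seed=2, n_compensatory=0, mutation_rate=0.0)
        ann = annotate_core(msa)
        assert "covariant" not in set(ann.conservation)

    def test_genus_specific_pseudoknot_lost_in_joint_alignment(self):
        """Two lineages whose pseudoknot arms differ in sequence but not
        position each yield a PK alone; stacked together the pairing
        fraction collapses and the joint alignment yields none."""
        msa_a, truth_a = make_tr_core_family(n_rows=8, seed=3)
        t1 = truth_a["template_columns"][1]
        p1c3_start = truth_a["stems"]["p1c"][-1][1]
        # lineage B: the whole pseudoknot region shifted 2 columns 5'-ward
        rows_b = [
            r[:t1] + r[t1 + 2 : p1c3_start] + r[t1 : t1 + 2] + r[p1c3_start:]
            for r in msa_a.rows
        ]
        msa_b = CoreMSA([f"b{i}" for i in range(len(rows_b))], rows_b,
                        msa_a.template_columns)
        ann_a, ann_b = annotate_core(msa_a), annotate_core(msa_b)
        assert ann_a.p2 == truth_a["stems"]["p2"]
        assert ann_b.p2 and ann_b.p2 != ann_a.p2  # positionally shifted PK
        joint = CoreMSA(
            msa_a.ids + msa_b.ids, msa_a.rows + msa_b.rows, msa_a.template_columns
        )
        ann_joint = annotate_core(joint)
        # neither lineage's pseudoknot survives the joint alignment; at most
        # fragmentary chance pairing remains
        assert ann_joint.p2 != ann_a.p2 and ann_joint.p2 != ann_b.p2
        assert len(ann_joint.p2) + len(ann_joint.p3) < len(ann_a.p2) + len(ann_a.p3)
        # the 5' elements, untouched by the shift, remain conserved
        assert ann_joint.p1_1 == ann_a.p1_1

    def test_row_permutation_invariance(self):
        msa, _ = make_tr_core_family(n_rows=10, seed=5)
        perm = np.random.default_rng(0).permutation(10)
        shuffled = CoreMSA(
            [msa.ids[i] for i in perm], [msa.rows[i] for i in perm], msa.template_columns
        )
        a1, a2 = annotate_core(msa), annotate_core(shuffled)
        assert a1.stems() == a2.stems()
        assert a1.conservation == a2.conservation

    def test_reported_pairs_satisfy_pairing_criterion(self):
        comp_pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
        msa, _ = make_tr_core_family(n_rows=10, seed=6)
        ann = annotate_core(msa)
        for pairs in ann.stems().values():
            for i, j in pairs:
                ok = sum((r[i], r[j]) in comp_pairs for r in msa.rows)
                assert ok / msa.n_rows >= 0.9

    def test_pseudoknot_interleaving_constraint(self):
        msa, _ = make_tr_core_family(n_rows=10, seed=7)
        ann = annotate_core(msa)
        a = ann.p2[-1][0]
        b = ann.p3[0][0]
        c = ann.p2[-1][1]
        d = ann.p3[0][1]
        assert a < b < c < d

    def test_dot_bracket_output(self):
        msa, _ = make_tr_core_family(n_rows=10, seed=8)
        ann = annotate_core(msa)
        db = dot_bracket(ann, msa.n_columns)
        assert len(db) == msa.n_columns
        assert db.count("[") == len(ann.p3)
        assert db.count("(") == len(ann.p1c) + len(ann.p1_1) + len(ann.p2)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            CoreMSA(["a", "b"], ["ACGU", "ACG"], (0, 1))
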