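"""Masking, gap-aware haplotype collapsing, and combination haplotypes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hapresolve as hr
from hapresolve.core_io import DataError

from conftest import make_alignment


def brute_force_partition(seqs):
    """Independent O(n^2) oracle: group by all-pairs string identity."""
    ids = list(seqs)
    groups = []
    for sid in ids:
        for g in groups:
            if all(seqs[sid] == seqs[other] for other in g):
                g.append(sid)
                break
        else:
            groups.append([sid])
    return {frozenset(g) for g in groups}


def random_alignment(rng, n, length, n_templates=6, gap_prob=0.05):
    templates = [
        "".join(rng.choice(list("ACGT"), length)) for _ in range(n_templates)
    ]
    seqs = {}
    for i in range(n):
        t = list(templates[rng.integers(n_templates)])
        for c in range(length):
            if rng.random() < gap_prob:
                t[c] = "-"
            elif rng.random() < 0.02:
                t[c] = "ACGT"[rng.integers(4)]
        seqs[f"s{i:03d}"] = "".join(t)
    return seqs


class TestApplyMasks:
    def test_unalignable_block_trimmed(self):
        """A 306-column marker with a 26-column unalignable mask analyzes
        at 280 columns."""
        seq = "ACGT" * 76 + "AC"  # 306
        aln = make_alignment({"a": seq, "b": seq}, masks=[hr.MaskInterval(50, 75)])
        out = hr.apply_masks(aln)
        assert aln.length == 306 and out.length == 280
        assert out.masks == ()

    def test_single_ambiguous_column(self):
        """An 854-column marker with one masked ambiguous column analyzes
        at 853."""
        seq = "A" * 854
        aln = make_alignment(
            {"a": seq}, masks=[hr.MaskInterval(35, 35, "ambiguous")]
        )
        assert hr.apply_masks(aln).length == 853

    def test_no_masks_is_identity(self):
        aln = make_alignment(["ACGT", "AC-T"])
        assert hr.apply_masks(aln) is aln

    def test_overlapping_masks_merged(self):
        aln = make_alignment(
            ["ACGTACGTAC"], masks=[hr.MaskInterval(2, 5), hr.MaskInterval(4, 7)]
        )
        assert hr.apply_masks(aln).length == 4

    def test_out_of_bounds_mask_rejected(self):
        with pytest.raises(ValueError):
            make_alignment(["ACGT"], masks=[hr.MaskInterval(2, 9)])

    def test_masked_columns_removed_not_replaced(self):
        aln = make_alignment({"a": "AXGT".replace("X", "C")},
                             masks=[hr.MaskInterval(2, 2)])
        assert hr.apply_masks(aln).sequences["a"] == "AGT"


class TestCollapseHaplotypes:
    def test_identical_sequences_share_a_class(self):
        aln = make_alignment(["ACGT", "ACGT", "ACTT"])
        a = hr.collapse_haplotypes(aln)
        assert a.labels == {"s1": 1, "s2": 1, "s3": 2}
        assert a.n_classes == 2

    def test_gap_difference_separates(self):
        a = hr.collapse_haplotypes(make_alignment(["AC-T", "ACGT"]))
        assert a.n_classes == 2

    def test_ambiguity_codes_compare_literally(self):
        a = hr.collapse_haplotypes(make_alignment(["ACRT", "ACAT"]))
        assert a.n_classes == 2

    def test_empty_alignment_rejected(self):
        with pytest.raises(DataError):
            hr.collapse_haplotypes(make_alignment({}))

    def test_matches_all_pairs_oracle_on_200_sequences(self):
        rng = np.random.default_rng(42)
        seqs = random_alignment(rng, 200, 120)
        got = hr.collapse_haplotypes(make_alignment(seqs))
        assert set(got.class_members.values()) == brute_force_partition(seqs)


class TestCombineMarkers:
    def test_single_marker_is_identity(self, reference_assignments):
        a = reference_assignments["MutS"]
        assert hr.combine_markers([a]) is a

    def test_one_differing_marker_splits_a_class(self):
        a1 = hr.collapse_haplotypes(make_alignment({"x": "AAAA", "y": "AAAA"}))
        a2 = hr.collapse_haplotypes(make_alignment({"x": "CCCC", "y": "CCCT"}))
        combo = hr.combine_markers([a1, a2])
        assert combo.n_classes == 2

    def test_specimen_set_mismatch_lists_difference(self):
        a1 = hr.collapse_haplotypes(make_alignment({"x": "AAAA", "y": "AAAA"}))
        a2 = hr.collapse_haplotypes(make_alignment({"x": "CCCC", "z": "CCCT"}))
        with pytest.raises(DataError, match="z"):
            hr.combine_markers([a1, a2])

    def test_fixture_combination_matches_printed_classes(self, reference):
        """Specimens with per-marker tuples (3,3,3,3,3) and (3,3,20,3,3)
        fall into two combination classes."""
        records, codes = reference
        sub = codes.loc[["1075468", "1075471", "1080454"]]
        combo = hr.combination_from_codes(sub)
        assert combo.labels["1075468"] == combo.labels["1075471"]
        assert combo.labels["1080454"] != combo.labels["1075468"]

    def test_refinement_on_fixture(self, reference, reference_assignments):
        _, codes = reference
        combo = hr.combination_from_codes(codes)
        singles = max(a.n_classes for a in reference_assignments.values())
        assert combo.n_classes == 27 >= singles


class TestCombinationFromCodes:
    def test_narella_rows_give_17_classes(self, reference):
        records, codes = reference
        narella = [r.specimen_id for r in records if r.genus == "Narella"]
        assert len(narella) == 39
        assert hr.combination_from_codes(codes.loc[narella]).n_classes == 17

    def test_one_specimen_one_class(self):
        assert hr.combination_from_codes({"a": (1, 2, 3)}).n_classes == 1

    def test_tuples_differing_in_one_marker_split(self):
        combo = hr.combination_from_codes({"a": (1, 2), "b": (1, 3)})
        assert combo.n_classes == 2

    def test_ragged_tuples_rejected(self):
        with pytest.raises(DataError, match="ragged"):
            hr.combination_from_codes({"a": (1, 2), "b": (1,)})


@st.composite
def code_tables(draw):
    n = draw(st.integers(2, 12))
    arity = draw(st.integers(1, 4))
    return {
        f"s{i}": tuple(
            draw(st.integers(1, 3)) for _ in range(arity)
        )
        for i in range(n)
    }


class TestPartitionProperties:
    @given(code_tables())
    @settings(max_examples=100, deadline=None)
    def test_partition_and_refinement(self, table):
        """Classes partition the specimens, and the combination has at
        least as many classes as any single marker."""
        combo = hr.combination_from_codes(table)
        members = combo.class_members
        all_ids = set()
        for group in members.values():
            assert not (all_ids & group)
            all_ids |= group
        assert all_ids == set(table)
        arity = len(next(iter(table.values())))
        for k in range(arity):
            single = hr.combination_from_codes(
                {sid: (t[k],) for sid, t in table.items()}
            )
            assert combo.n_classes >= single.n_classes
            # refinement: each combination class sits inside one single class
            for group in members.values():
                assert len({single.labels[sid] for sid in group}) == 1

    @given(code_tables(), st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_label_invariance(self, table, rnd):
        """Relabeling marker codes never changes the induced partition."""
        arity = len(next(iter(table.values())))
        perms = []
        for k in range(arity):
            values = sorted({t[k] for t in table.values()})
            shuffled = values[:]
            rnd.shuffle(shuffled)
            perms.append(dict(zip(values, shuffled)))
        relabeled = {
            sid: tuple(perms[k][t[k]] for k in range(arity))
            for sid, t in table.items()
        }
        a = hr.combination_from_codes(table)
        b = hr.combination_from_codes(relabeled)
        assert set(a.class_members.values()) == set(b.class_members.values())
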