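"""Incidence matrices, the fully-resolved-species statistic, and
diagnostic characters."""

import numpy as np
import pytest

import hapresolve as hr
from hapresolve.resolution import round_half_up_pct

from conftest import make_alignment

MARKERS = ["NCR1", "ND6", "ND2", "COI+", "MutS"]


def specimen(sid, species, genus=None, status="identified", **kw):
    defaults = dict(site="S", region="R", depth=hr.parse_depth("100"))
    defaults.update(kw)
    return hr.SpecimenRecord(
        specimen_id=sid, species=species,
        genus=genus or species.split()[0], id_status=status, **defaults
    )


class TestIncidence:
    def test_fixture_focal_matrix_shape(self, reference, reference_assignments):
        """12 identified focal morphotypes against 8 haplotype classes."""
        records, _ = reference
        m = hr.incidence(reference_assignments["NCR1"], records, "Narella")
        assert len(m.species) == 12
        assert len(m.haplotypes) == 8
        assert not (m.counts.sum(axis=1) == 0).any()
        assert not (m.counts.sum(axis=0) == 0).any()

    def test_unidentified_specimens_tallied_separately(self, reference,
                                                       reference_assignments):
        records, _ = reference
        m = hr.incidence(reference_assignments["NCR1"], records, "Narella")
        assert "Narella sp." not in m.species
        n_unident = sum(
            1 for r in records
            if r.genus == "Narella" and r.id_status == "unidentified"
        )
        assert sum(m.unassigned.values()) == n_unident == 5
        assert int(m.counts.to_numpy().sum()) == 39 - 5

    def test_single_cell(self):
        specs = [specimen("a", "G x")]
        a = hr.combination_from_codes({"a": (1,)})
        m = hr.incidence(a, specs)
        assert m.counts.shape == (1, 1)


class TestResolvedSpecies:
    def test_shared_haplotype_blocks_both(self):
        specs = [specimen("a", "G a"), specimen("b", "G b"), specimen("c", "G c")]
        a = hr.combination_from_codes({"a": (1,), "b": (1,), "c": (2,)})
        assert hr.resolved_species(a, specs) == {"G c"}

    def test_exclusive_haplotypes_all_resolved(self):
        specs = [specimen("a", "G a"), specimen("b", "G b")]
        a = hr.combination_from_codes({"a": (1,), "b": (2,)})
        assert hr.resolved_species(a, specs) == {"G a", "G b"}

    def test_fixture_ncr1_resolves_two(self, reference, reference_assignments):
        records, _ = reference
        resolved = hr.resolved_species(
            reference_assignments["NCR1"], records, "Narella"
        )
        assert len(resolved) == 2
        assert resolved == {"Narella dichotoma", "Narella macrocalyx"}

    def test_cross_genus_sharing_blocks(self):
        """A haplotype shared with a different genus blocks resolution
        under dataset-wide scope but not under genus-restricted scope."""
        specs = [specimen("a", "GA x"), specimen("b", "GB y")]
        a = hr.combination_from_codes({"a": (1,), "b": (1,)})
        assert hr.resolved_species(a, specs, "GA", "dataset") == set()
        assert hr.resolved_species(a, specs, "GA", "genus") == {"GA x"}

    def test_genus_scope_never_resolves_fewer(self, reference,
                                              reference_assignments):
        records, _ = reference
        for a in reference_assignments.values():
            dataset = hr.resolved_species(a, records, "Narella", "dataset")
            genus_only = hr.resolved_species(a, records, "Narella", "genus")
            assert dataset <= genus_only

    def test_sharing_partners_identified(self, reference, reference_assignments):
        records, _ = reference
        from hapresolve.resolution import sharing_partners

        shared = sharing_partners(
            reference_assignments["NCR1"], records, "Narella alata"
        )
        others = {t for ts in shared.values() for t in ts}
        assert "Narella sp. 1" in others
        assert any(t.startswith("Parastenella") or t.startswith("Primnoa")
                   for t in others)


class TestResolutionSummary:
    def test_fixture_counts_match_printed_table(self, reference,
                                                reference_assignments):
        records, _ = reference
        subsets = [(m,) for m in MARKERS] + [tuple(MARKERS)]
        rep = hr.resolution_summary(
            reference_assignments, subsets, records, "Narella"
        )
        resolved = [rep[s].n_species_resolved
                    for s in MARKERS + ["+".join(MARKERS)]]
        assert resolved == [2, 3, 4, 6, 6, 10]
        assert rep["+".join(MARKERS)].pct_resolved == 83

    def test_extended_barcode_subsets(self, reference, reference_assignments):
        records, _ = reference
        rep = hr.resolution_summary(
            reference_assignments,
            [("COI+", "MutS"), ("COI+", "MutS", "ND2")],
            records, "Narella",
        )
        assert rep["COI++MutS"].n_species_resolved == 9
        assert rep["COI++MutS+ND2"].n_species_resolved == 10

    def test_monotone_under_subset_growth(self, reference,
                                          reference_assignments):
        """Adding markers only refines the partition, so the resolved set
        can only grow: MutS -> +COI+ -> +ND2 -> all five."""
        records, _ = reference
        chain = [("MutS",), ("COI+", "MutS"), ("COI+", "MutS", "ND2"),
                 tuple(MARKERS)]
        rep = hr.resolution_summary(reference_assignments, chain, records,
                                    "Narella")
        sets = [set(rep["+".join(s)].resolved) for s in chain]
        assert [len(s) for s in sets] == [6, 9, 10, 10]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_single_species_dataset(self):
        specs = [specimen("a", "G x"), specimen("b", "G x")]
        assigns = {"m": hr.combination_from_codes({"a": (1,), "b": (1,)},
                                                  marker_set=("m",))}
        rep = hr.resolution_summary(assigns, [("m",)], specs)
        assert rep["m"].n_species_total == 1
        assert rep["m"].pct_resolved in (0, 100)

    def test_empty_subset_rejected(self, reference, reference_assignments):
        records, _ = reference
        with pytest.raises(ValueError):
            hr.resolution_summary(reference_assignments, [()], records)

    def test_unresolved_list_names_blockers(self, reference,
                                            reference_assignments):
        records, _ = reference
        rep = hr.resolution_summary(
            reference_assignments, [tuple(MARKERS)], records, "Narella"
        )
        unresolved = rep["+".join(MARKERS)].unresolved
        assert set(unresolved) == {
            "Narella arbuscula", "Narella sp. cf. macrocalyx"
        }
        assert "Narella arbuscula" in unresolved["Narella sp. cf. macrocalyx"]


@pytest.mark.parametrize(
    "numer, denom, expected",
    [(2, 12, 17), (3, 12, 25), (6, 12, 50), (10, 12, 83), (9, 12, 75),
     (1, 8, 13), (0, 5, 0), (5, 5, 100)],
)
def test_round_half_up_pct(numer, denom, expected):
    assert round_half_up_pct(numer, denom) == expected


class TestDiagnosticSites:
    def test_fixed_private_state_found(self):
        specs = [specimen("a", "G x"), specimen("b", "G x"),
                 specimen("c", "G y")]
        aln = make_alignment({"a": "ACGTT", "b": "ACGTT", "c": "ACGTC"})
        assert hr.diagnostic_sites(aln, specs, "G x") == [(5, "T")]
        assert hr.diagnostic_sites(aln, specs, "G y") == [(5, "C")]

    def test_shared_states_yield_nothing(self):
        specs = [specimen("a", "G x"), specimen("b", "G y")]
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert hr.diagnostic_sites(aln, specs, "G x") == []

    def test_gap_state_can_be_diagnostic(self):
        specs = [specimen("a", "G x"), specimen("b", "G y")]
        aln = make_alignment({"a": "AC-T", "b": "ACGT"})
        assert (3, "-") in hr.diagnostic_sites(aln, specs, "G x")

    def test_unknown_species_rejected(self):
        specs = [specimen("a", "G x")]
        aln = make_alignment({"a": "ACGT"})
        with pytest.raises(hr.DataError):
            hr.diagnostic_sites(aln, specs, "G zz")

    def test_matches_exhaustive_scan_on_synthetic_data(self):
        """Agreement with an independent per-column scan over a 30-species
        alignment."""
        rng = np.random.default_rng(3)
        specs, seqs = [], {}
        for sp in range(30):
            base = rng.choice(list("ACGT"), 80)
            for i in range(2):
                sid = f"s{sp}_{i}"
                specs.append(specimen(sid, f"G sp{sp}"))
                seqs[sid] = "".join(base)
        aln = make_alignment(seqs)
        for sp_label in ("G sp0", "G sp17", "G sp29"):
            got = hr.diagnostic_sites(aln, specs, sp_label)
            expected = []
            in_ids = [s.specimen_id for s in specs if s.species == sp_label]
            out_ids = [s.specimen_id for s in specs if s.species != sp_label]
            for col in range(aln.length):
                states = {seqs[i][col] for i in in_ids}
                if len(states) == 1:
                    (state,) = states
                    if state not in {seqs[o][col] for o in out_ids}:
                        expected.append((col + 1, state))
            assert got == expected
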