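"""The species-resolution statistic and diagnostic character identification.

A morphological species is "fully resolved" by a marker (or marker subset)
when every haplotype observed in that species occurs in no specimen of any
other taxon in the dataset.  This is a character-based criterion — species
are told apart by exclusive sequence classes, not by a distance threshold —
and it is deliberately evaluated against the ENTIRE dataset, other genera
included: a haplotype shared with a different genus blocks resolution just
as one shared with a congener does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import AlignedMarkerSet, DataError, SpecimenRecord
from .haplotypes import HaplotypeAssignment, combine_markers


def round_half_up_pct(numer: int, denom: int) -> int:
    """Integer percentage with exact half-up rounding (2/12 -> 17)."""
    if denom == 0:
        return 0
    return int(math.floor(100.0 * numer / denom + 0.5))


@dataclass(frozen=True)
class IncidenceMatrix:
    """Specimen counts per (species, haplotype code).

    Rows are identified species of the requested scope; unidentified
    specimens are tallied separately in ``unassigned`` (code → count)
    rather than given rows.
    """

    counts: pd.DataFrame  # rows: species; cols: int haplotype codes
    scope: str  # 'identified-only' description of the row filter
    unassigned: Mapping[int, int] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotypes(self) -> list[int]:
        return list(self.counts.columns)


def incidence(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
    focal_genus: str | None = None,
) -> IncidenceMatrix:
    """Cross-tabulate species (rows) against haplotype codes (columns).

    Only identified specimens of the focal genus (all genera when None)
    get rows; unidentified specimens are counted in the unassigned tally.
    """
    covered = [s for s in specimens if s.specimen_id in assignment.labels]
    if len(covered) < len(list(specimens)):
        missing = [s.specimen_id for s in specimens
                   if s.specimen_id not in assignment.labels]
        raise DataError(f"specimens missing from assignment: {missing}")
    scoped = [
        s for s in covered
        if s.id_status == "identified"
        and (focal_genus is None or s.genus == focal_genus)
    ]
    unassigned: dict[int, int] = {}
    for s in covered:
        if s.id_status == "unidentified" and (
            focal_genus is None or s.genus == focal_genus
        ):
            code = assignment.labels[s.specimen_id]
            unassigned[code] = unassigned.get(code, 0) + 1
    rows = sorted({s.species for s in scoped})
    cols = sorted({assignment.labels[s.specimen_id] for s in scoped})
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for s in scoped:
        counts.loc[s.species, assignment.labels[s.specimen_id]] += 1
    return IncidenceMatrix(
        counts=counts,
        scope=(f"identified {focal_genus}" if focal_genus else "identified, all genera"),
        unassigned=unassigned,
    )


def _haplotype_owners(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
    include_unidentified: bool,
) -> dict[int, set[str]]:
    """Map each haplotype code to the taxa observed carrying it.

    Identified specimens contribute their species label; unidentified ones
    (when included) contribute a per-specimen pseudo-taxon, since nothing
    is known about their conspecificity.
    """
    owners: dict[int, set[str]] = {}
    for s in specimens:
        if s.specimen_id not in assignment.labels:
            continue
        if s.id_status == "identified":
            owner = s.species
        elif include_unidentified:
            owner = f"unidentified:{s.specimen_id}"
        else:
            continue
        owners.setdefault(assignment.labels[s.specimen_id], set()).add(owner)
    return owners


def resolved_species(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
    focal_genus: str | None = None,
    uniqueness_scope: str = "dataset",
    include_unidentified: bool = False,
) -> set[str]:
    """Species whose every observed haplotype is exclusive to them.

    ``uniqueness_scope`` is ``"dataset"`` (default: sharing with ANY taxon,
    other genera included, blocks resolution) or ``"genus"`` (sensitivity
    analysis restricted to the focal genus).  ``include_unidentified``
    lets unidentified specimens' haplotypes count against exclusivity.
    """
    if uniqueness_scope not in ("dataset", "genus"):
        raise ValueError(f"bad uniqueness_scope: {uniqueness_scope!r}")
    universe = [
        s for s in specimens
        if uniqueness_scope == "dataset"
        or focal_genus is None
        or s.genus == focal_genus
    ]
    owners = _haplotype_owners(assignment, universe, include_unidentified)
    focal = [
        s for s in specimens
        if s.id_status == "identified"
        and (focal_genus is None or s.genus == focal_genus)
    ]
    used: dict[str, set[int]] = {}
    for s in focal:
        used.setdefault(s.species, set()).add(assignment.labels[s.specimen_id])
    return {
        sp for sp, codes in used.items()
        if all(owners.get(h, set()) == {sp} for h in codes)
    }


def sharing_partners(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
    species: str,
    include_unidentified: bool = False,
) -> dict[int, set[str]]:
    """For one species, the other taxa sharing each of its haplotypes."""
    owners = _haplotype_owners(assignment, specimens, include_unidentified)
    used = {
        assignment.labels[s.specimen_id]
        for s in specimens
        if s.species == species and s.id_status == "identified"
    }
    out = {}
    for h in used:
        others = owners.get(h, set()) - {species}
        if others:
            out[h] = others
    return out


@dataclass(frozen=True)
class SubsetResolution:
    """Resolution statistics for one marker subset (one Table column)."""

    markers: tuple[str, ...]
    n_haplotypes_total: int
    n_haplotypes_focal: int
    n_species_resolved: int
    n_species_total: int
    pct_resolved: int
    resolved: tuple[str, ...]
    unresolved: Mapping[str, tuple[str, ...]]  # species -> blocking taxa
    analyzed_length: int | None = None

    @property
    def name(self) -> str:
        return "+".join(self.markers)


@dataclass(frozen=True)
class ResolutionReport:
    """Per-marker-subset resolution summary (the marker evaluation table)."""

    focal_genus: str | None
    subsets: tuple[SubsetResolution, ...]

    def __getitem__(self, name: str) -> SubsetResolution:
        for s in self.subsets:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "analyzed_length": {},
            "n_haplotypes": {},
            "n_haplotypes_focal": {},
            "n_species_resolved": {},
            "n_species_total": {},
            "pct_resolved": {},
        }
        for s in self.subsets:
            rows["analyzed_length"][s.name] = (
                s.analyzed_length if s.analyzed_length is not None else ""
            )
            rows["n_haplotypes"][s.name] = s.n_haplotypes_total
            rows["n_haplotypes_focal"][s.name] = s.n_haplotypes_focal
            rows["n_species_resolved"][s.name] = s.n_species_resolved
            rows["n_species_total"][s.name] = s.n_species_total
            rows["pct_resolved"][s.name] = s.pct_resolved
        df = pd.DataFrame(rows).T
        return df[[s.name for s in self.subsets]]

    def to_dict(self) -> dict:
        return {
            "focal_genus": self.focal_genus,
            "subsets": {
                s.name: {
                    "markers": list(s.markers),
                    "analyzed_length": s.analyzed_length,
                    "n_haplotypes": s.n_haplotypes_total,
                    "n_haplotypes_focal": s.n_haplotypes_focal,
                    "n_species_resolved": s.n_species_resolved,
                    "n_species_total": s.n_species_total,
                    "pct_resolved": s.pct_resolved,
                    "resolved": sorted(s.resolved),
                    "unresolved": {
                        sp: sorted(blockers)
                        for sp, blockers in sorted(s.unresolved.items())
                    },
                }
                for s in self.subsets
            },
        }


def resolution_summary(
    assignments: Mapping[str, HaplotypeAssignment],
    subsets: Sequence[Sequence[str]],
    specimens: Sequence[SpecimenRecord],
    focal_genus: str | None = None,
    uniqueness_scope: str = "dataset",
    include_unidentified: bool = False,
    analyzed_lengths: Mapping[str, int] | None = None,
) -> ResolutionReport:
    """Score each requested marker subset.

    ``assignments`` maps single-marker names to their haplotype partitions;
    each subset (e.g. ``["COI+", "MutS"]``) is scored on the combination
    partition built from its members.  Resolved counts are monotone
    non-decreasing as subsets grow, because combinations only refine.
    """
    focal_species = sorted({
        s.species for s in specimens
        if s.id_status == "identified"
        and (focal_genus is None or s.genus == focal_genus)
    })
    results = []
    for subset in subsets:
        markers = tuple(subset)
        if not markers:
            raise ValueError("empty marker subset")
        unknown = [m for m in markers if m not in assignments]
        if unknown:
            raise KeyError(f"unknown marker(s): {unknown}")
        combo = combine_markers([assignments[m] for m in markers])
        resolved = resolved_species(
            combo, specimens, focal_genus, uniqueness_scope, include_unidentified
        )
        unresolved = {}
        for sp in focal_species:
            if sp in resolved:
                continue
            partners = sharing_partners(combo, specimens, sp, include_unidentified)
            unresolved[sp] = tuple(sorted({t for ts in partners.values() for t in ts}))
        focal_ids = {
            s.specimen_id for s in specimens
            if focal_genus is None or s.genus == focal_genus
        }
        n_focal = len({
            code for sid, code in combo.labels.items() if sid in focal_ids
        })
        length = None
        if analyzed_lengths is not None:
            try:
                length = sum(analyzed_lengths[m] for m in markers)
            except KeyError:
                length = None
        results.append(
            SubsetResolution(
                markers=markers,
                n_haplotypes_total=combo.n_classes,
                n_haplotypes_focal=n_focal,
                n_species_resolved=len(resolved),
                n_species_total=len(focal_species),
                pct_resolved=round_half_up_pct(len(resolved), len(focal_species)),
                resolved=tuple(sorted(resolved)),
                unresolved=unresolved,
                analyzed_length=length,
            )
        )
    return ResolutionReport(focal_genus=focal_genus, subsets=tuple(results))


def diagnostic_sites(
    alignment: AlignedMarkerSet,
    specimens: Sequence[SpecimenRecord],
    species: str,
) -> list[tuple[int, str]]:
    """Pure diagnostic characters for one species.

    Returns 1-based columns where every specimen of the species shares one
    state (gap included) and no other specimen in the alignment carries
    that state.  Compound (multi-column) diagnostics are out of scope.
    """
    in_ids = [
        s.specimen_id for s in specimens
        if s.species == species and s.specimen_id in alignment.sequences
    ]
    if not in_ids:
        raise DataError(f"unknown or unsequenced species: {species!r}")
    out_ids = [sid for sid in alignment.specimen_ids if sid not in set(in_ids)]
    sites = []
    for col in range(alignment.length):
        states_in = {alignment.sequences[i][col] for i in in_ids}
        if len(states_in) != 1:
            continue
        state = next(iter(states_in))
        if all(alignment.sequences[o][col] != state for o in out_ids):
            sites.append((col + 1, state))
    return sites
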