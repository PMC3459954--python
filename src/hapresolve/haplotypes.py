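"""Masking, haplotype collapsing, and combination haplotypes.

A haplotype is a unique aligned sequence class for one marker: two specimens
carry the same haplotype only if their masked sequences are identical in
every column, with the gap character '-' treated as a fifth state (one
nucleotide difference OR a gap difference separates haplotypes).  A
combination haplotype is joint identity across several markers —
equivalently, equality of the per-marker haplotype code tuple — and is the
finest partition a marker set supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import AlignedMarkerSet, DataError, MaskInterval

logger = logging.getLogger("hapresolve")


@dataclass(frozen=True)
class HaplotypeAssignment:
    """A partition of specimens into numbered haplotype classes.

    Codes are positive integers 1..n_classes assigned by order of first
    occurrence in input order, so the numbering is deterministic but
    arbitrary; every downstream statistic is invariant under relabeling.
    """

    marker_set: tuple[str, ...]
    labels: Mapping[str, int]

    def __post_init__(self) -> None:
        codes = sorted(set(self.labels.values()))
        if codes and codes != list(range(1, len(codes) + 1)):
            raise ValueError("haplotype codes must be 1..n with no gaps")

    @property
    def n_classes(self) -> int:
        return len(set(self.labels.values()))

    @property
    def class_members(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for sid, code in self.labels.items():
            out.setdefault(code, set()).add(sid)
        return {c: frozenset(m) for c, m in out.items()}

    @property
    def specimen_ids(self) -> frozenset[str]:
        return frozenset(self.labels)


def _first_occurrence_codes(
    keys: Sequence[object], ids: Sequence[str], marker_set: tuple[str, ...]
) -> HaplotypeAssignment:
    code_of: dict[object, int] = {}
    labels: dict[str, int] = {}
    for sid, key in zip(ids, keys):
        if key not in code_of:
            code_of[key] = len(code_of) + 1
        labels[sid] = code_of[key]
    return HaplotypeAssignment(marker_set=marker_set, labels=labels)


def apply_masks(alignment: AlignedMarkerSet) -> AlignedMarkerSet:
    """Remove masked columns and return the trimmed alignment.

    Overlapping or touching mask intervals are merged first.  The result
    carries no masks; its length is the analyzed sequence length.
    """
    if not alignment.masks:
        return alignment
    merged: list[list[int]] = []
    for m in sorted(alignment.masks, key=lambda m: (m.start, m.end)):
        if m.end > alignment.length:
            raise ValueError(
                f"{alignment.marker}: mask {m.start}-{m.end} out of bounds"
            )
        if merged and m.start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], m.end)
        else:
            merged.append([m.start, m.end])
    drop = set()
    for start, end in merged:
        drop.update(range(start - 1, end))  # to 0-based
    keep = [c for c in range(alignment.length) if c not in drop]
    sequences = {
        sid: "".join(seq[c] for c in keep)
        for sid, seq in alignment.sequences.items()
    }
    logger.info(
        "%s: removed %d masked column(s), %d -> %d nt",
        alignment.marker, len(drop), alignment.length, len(keep),
    )
    return AlignedMarkerSet(
        marker=alignment.marker, sequences=sequences, length=len(keep), masks=()
    )


def collapse_haplotypes(alignment: AlignedMarkerSet) -> HaplotypeAssignment:
    """Group specimens with column-for-column identical sequences.

    Gap '-' is a first-class state and IUPAC ambiguity codes compare
    literally, so any single differing column — substitution or gap —
    separates haplotypes.  Mask known-ambiguous columns beforehand.
    """
    if not alignment.sequences:
        raise DataError(f"{alignment.marker}: cannot collapse an empty alignment")
    if alignment.masks:
        logger.warning(
            "%s: collapsing with %d unapplied mask(s); call apply_masks first",
            alignment.marker, len(alignment.masks),
        )
    ids = list(alignment.specimen_ids)
    return _first_occurrence_codes(
        [alignment.sequences[i] for i in ids], ids, (alignment.marker,)
    )


def combine_markers(
    assignments: Sequence[HaplotypeAssignment],
    order: Sequence[str] | None = None,
) -> HaplotypeAssignment:
    """Build the combination partition: joint identity across all markers.

    Two specimens share a combination class iff they share a class in every
    input marker.  All assignments must cover the same specimen set (drop
    specimens lacking any marker beforehand).  The result refines each
    input partition.
    """
    if not assignments:
        raise ValueError("combine_markers needs at least one assignment")
    by_marker = {a.marker_set[0] if len(a.marker_set) == 1 else a.marker_set: a
                 for a in assignments}
    if order is not None:
        missing = [m for m in order if m not in by_marker]
        if missing:
            raise ValueError(f"unknown marker(s) in order: {missing}")
        ordered = [by_marker[m] for m in order]
    else:
        ordered = list(assignments)

    base_ids = ordered[0].specimen_ids
    for a in ordered[1:]:
        if a.specimen_ids != base_ids:
            only_first = sorted(base_ids - a.specimen_ids)
            only_other = sorted(a.specimen_ids - base_ids)
            raise DataError(
                "specimen sets differ between markers "
                f"{ordered[0].marker_set} and {a.marker_set}: "
                f"only in first: {only_first}; only in other: {only_other}"
            )
    if len(ordered) == 1:
        return ordered[0]
    ids = list(ordered[0].labels)  # input order of the first marker
    tuples = [tuple(a.labels[sid] for a in ordered) for sid in ids]
    marker_set = tuple(m for a in ordered for m in a.marker_set)
    return _first_occurrence_codes(tuples, ids, marker_set)


def combination_from_codes(
    code_table: Mapping[str, tuple[int, ...]] | "pandas.DataFrame",
    marker_set: Iterable[str] | None = None,
) -> HaplotypeAssignment:
    """Build a (combination) assignment directly from integer code tuples.

    Accepts a specimen_id → tuple mapping or a DataFrame indexed by
    specimen_id with one column per marker, e.g. a pre-coded haplotype
    table read by :func:`hapresolve.core_io.read_specimen_table`.  With a
    single marker this simply renumbers that marker's codes.
    """
    import pandas as pd

    if isinstance(code_table, pd.DataFrame):
        markers = tuple(marker_set) if marker_set is not None else tuple(code_table.columns)
        sub = code_table[list(markers)]
        mapping = {sid: tuple(int(v) for v in row) for sid, row in sub.iterrows()}
    else:
        mapping = {sid: tuple(t) for sid, t in code_table.items()}
        markers = tuple(marker_set) if marker_set is not None else ()
    arities = {len(t) for t in mapping.values()}
    if len(arities) > 1:
        raise DataError(f"ragged code tuples: arities {sorted(arities)}")
    if not mapping:
        raise DataError("empty code table")
    if not markers:
        markers = tuple(f"marker{i + 1}" for i in range(next(iter(arities))))
    ids = list(mapping)
    return _first_occurrence_codes([mapping[i] for i in ids], ids, markers)
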