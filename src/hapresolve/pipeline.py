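"""Orchestration: mask -> collapse -> combine -> resolve -> distances -> ranges.

Two input modes.  ``sequences`` starts from one aligned FASTA per marker
plus a specimen metadata table; specimens lacking any requested marker are
dropped (logged), masks are applied, haplotypes collapsed per marker, and
distance summaries computed.  ``codes`` starts from a pre-coded haplotype
table (integer code per specimen per marker) and runs the same resolution
and range stages without sequence-level distances.  Both modes agree: a
code table realized as sequences yields the identical resolution report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import core_io, distances, haplotypes, ranges, resolution
from .core_io import DataError, MaskInterval, SpecimenRecord

logger = logging.getLogger("hapresolve")


def default_subsets(markers: Sequence[str]) -> list[tuple[str, ...]]:
    """Each single marker, the full combination, and — when present —
    the two-marker extended barcode {COI+, MutS} and its ND2 extension."""
    out: list[tuple[str, ...]] = [(m,) for m in markers]
    if len(markers) > 1:
        out.append(tuple(markers))
    have = set(markers)
    for extra in (("COI+", "MutS"), ("COI+", "MutS", "ND2")):
        if set(extra) <= have and len(extra) < len(markers):
            out.append(extra)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Options for one pipeline run."""

    mode: str  # 'codes' | 'sequences'
    specimens_path: str | Path
    outdir: str | Path
    marker_fastas: Mapping[str, str | Path] = field(default_factory=dict)
    masks: Mapping[str, tuple[MaskInterval, ...]] = field(default_factory=dict)
    focal_genus: str | None = None
    subsets: tuple[tuple[str, ...], ...] | None = None
    uniqueness_scope: str = "dataset"
    include_unidentified: bool = False
    cryptic_threshold: float = distances.CRYPTIC_THRESHOLD
    bin_width: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("codes", "sequences"):
            raise ValueError(f"bad mode: {self.mode!r}")
        if self.mode == "sequences" and not self.marker_fastas:
            raise ValueError("sequences mode needs at least one --marker")


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run produced, plus the paths written."""

    specimens: list[SpecimenRecord]
    assignments: Mapping[str, haplotypes.HaplotypeAssignment]
    combination: haplotypes.HaplotypeAssignment
    report: resolution.ResolutionReport
    distance_summaries: Mapping[str, distances.DistanceSummary] | None
    cryptic_flags: list[str]
    haplotype_ranges: list[ranges.HaplotypeRange]
    occupancy: ranges.OccupancyMatrix | None
    written: Mapping[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise type(exc)(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report files."""
    specimens, codes = _read_specimens(config)
    analyzed_lengths = None

    if config.mode == "codes":
        if codes is None:
            raise DataError(
                "[input] codes mode needs per-marker code columns in the "
                "specimen table"
            )
        markers = list(codes.columns)
        logger.info("input: %d specimens, %d code columns", len(specimens), len(markers))
        assignments = {
            m: haplotypes.combination_from_codes(codes[[m]], marker_set=(m,))
            for m in markers
        }
        masked = None
    else:
        markers = list(config.marker_fastas)
        alignments = _read_alignments(config)
        shared_ids = set(specimens_ids := [s.specimen_id for s in specimens])
        for m, aln in alignments.items():
            shared_ids &= set(aln.specimen_ids)
        dropped = sorted(set(specimens_ids) - shared_ids)
        if dropped:
            logger.info(
                "dropping %d specimen(s) lacking >=1 marker: %s",
                len(dropped), ", ".join(dropped),
            )
        specimens = [s for s in specimens if s.specimen_id in shared_ids]
        if not specimens:
            raise DataError("[input] no specimen has all requested markers")
        masked = {
            m: haplotypes.apply_masks(aln.subset(shared_ids))
            for m, aln in alignments.items()
        }
        analyzed_lengths = {m: a.length for m, a in masked.items()}
        logger.info(
            "masking: analyzed lengths %s",
            ", ".join(f"{m}={l}" for m, l in analyzed_lengths.items()),
        )
        assignments = {m: haplotypes.collapse_haplotypes(a) for m, a in masked.items()}

    for m in markers:
        logger.info("collapse: %s -> %d haplotypes", m, assignments[m].n_classes)

    subsets = (
        [tuple(s) for s in config.subsets]
        if config.subsets is not None
        else default_subsets(markers)
    )
    combination = _combine(assignments, markers)
    logger.info("combine: %d combination haplotypes", combination.n_classes)

    report = _resolve(config, assignments, subsets, specimens, analyzed_lengths)
    try:
        full = report["+".join(markers)]
    except KeyError:
        full = report.subsets[-1]
    logger.info(
        "resolution: %d/%d species resolved by the full combination (%d%%)",
        full.n_species_resolved, full.n_species_total, full.pct_resolved,
    )

    distance_summaries = None
    cryptic: list[str] = []
    if masked is not None:
        distance_summaries = _distances(masked, markers, specimens, config)
        for summ in distance_summaries.values():
            cryptic.extend(
                distances.flag_cryptic(summ, config.cryptic_threshold)
            )
        cryptic = sorted(set(cryptic))
        logger.info("distances: %d cryptic-species flag(s)", len(cryptic))

    hap_ranges = ranges.range_summary(combination, specimens)
    occupancy = None
    if any(s.depth.kind != "missing" for s in specimens):
        occupancy = ranges.depth_occupancy(combination, specimens, config.bin_width)
    logger.info("ranges: %d combination haplotype range(s)", len(hap_ranges))

    written = _write(config, specimens, assignments, combination, report,
                     distance_summaries, hap_ranges, occupancy)
    return ReportBundle(
        specimens=specimens,
        assignments=assignments,
        combination=combination,
        report=report,
        distance_summaries=distance_summaries,
        cryptic_flags=cryptic,
        haplotype_ranges=hap_ranges,
        occupancy=occupancy,
        written=written,
    )


@_stage("input")
def _read_specimens(config: RunConfig):
    return core_io.read_specimen_table(config.specimens_path)


@_stage("input")
def _read_alignments(config: RunConfig):
    return {
        m: core_io.read_marker_alignment(p, m, config.masks.get(m, ()))
        for m, p in config.marker_fastas.items()
    }


@_stage("combine")
def _combine(assignments, markers):
    if len(markers) == 1:
        return assignments[markers[0]]
    return haplotypes.combine_markers([assignments[m] for m in markers])


@_stage("resolution")
def _resolve(config, assignments, subsets, specimens, analyzed_lengths):
    return resolution.resolution_summary(
        assignments, subsets, specimens,
        focal_genus=config.focal_genus,
        uniqueness_scope=config.uniqueness_scope,
        include_unidentified=config.include_unidentified,
        analyzed_lengths=analyzed_lengths,
    )


@_stage("distances")
def _distances(masked, markers, specimens, config):
    out: dict[str, distances.DistanceSummary] = {}
    for m in markers:
        mat = distances.pairwise_matrix(masked[m])
        out[m] = distances.level_summary(
            mat, specimens, config.focal_genus, marker=m
        )
    if len(markers) > 1:
        ids = masked[markers[0]].specimen_ids
        concat = core_io.AlignedMarkerSet(
            marker="+".join(markers),
            sequences={
                sid: "".join(masked[m].sequences[sid] for m in markers)
                for sid in ids
            },
            length=sum(masked[m].length for m in markers),
        )
        mat = distances.pairwise_matrix(concat)
        out[concat.marker] = distances.level_summary(
            mat, specimens, config.focal_genus, marker=concat.marker
        )
    return out


@_stage("write")
def _write(config, specimens, assignments, combination, report,
           distance_summaries, hap_ranges, occupancy):
    outdir = Path(config.outdir)
    try:
        return core_io.write_reports(
            outdir, specimens, assignments, combination, report,
            distance_summaries=distance_summaries,
            ranges=hap_ranges, occupancy=occupancy,
        )
    except Exception:
        for name in ("haplotype_table.tsv", "marker_summary.tsv",
                     "report.json", "depth_occupancy.tsv"):
            p = outdir / name
            if p.exists():
                p.unlink()
        raise
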