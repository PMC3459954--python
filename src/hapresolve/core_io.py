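"""Domain types and I/O for specimen metadata and aligned marker sequences.

The analysis operates on two kinds of input: a specimen metadata table
(one row per collected colony, with optional pre-assigned integer haplotype
codes per marker) and one multiple sequence alignment per mitochondrial
marker.  Everything downstream — haplotype collapsing, the resolution
statistic, distances, range summaries — consumes the types defined here.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("hapresolve")

#: Unambiguous DNA bases.
BASES = frozenset("ACGT")
#: IUPAC ambiguity codes (everything that is not a concrete base or a gap).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
#: Full alphabet accepted in alignments; 'U' is deliberately absent (DNA only).
ALPHABET = BASES | AMBIGUITY_CODES | {"-"}

#: Reserved metadata columns; anything else in a specimen table is taken to
#: be a per-marker haplotype code column.
RESERVED_COLUMNS = (
    "specimen_id",
    "species",
    "genus",
    "id_status",
    "site",
    "region",
    "lat",
    "lon",
    "depth",
)

REQUIRED_COLUMNS = (
    "specimen_id",
    "species",
    "genus",
    "id_status",
    "site",
    "region",
    "depth",
)


class FormatError(ValueError):
    """Malformed input file (missing column, bad alphabet, ragged alignment)."""


class DataError(ValueError):
    """Structurally valid input that violates a dataset invariant."""


# --------------------------------------------------------------------------
# Depth observations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthObservation:
    """A collection depth in meters.

    ``kind`` records how the point estimate was obtained: ``exact`` for a
    single recorded depth, ``range_midpoint`` when only a dive depth range
    was available and the midpoint is used, ``missing`` otherwise.
    ``uncertain`` marks depths the collectors themselves questioned
    (a trailing "?" in the source record).
    """

    value_m: float | None
    kind: str  # 'exact' | 'range_midpoint' | 'missing'
    raw: str
    uncertain: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "range_midpoint", "missing"):
            raise ValueError(f"bad depth kind: {self.kind!r}")
        if self.kind == "missing":
            if self.value_m is not None:
                raise ValueError("missing depth must not carry a value")
        elif self.value_m is None or self.value_m <= 0:
            raise ValueError("depth value must be positive when present")


_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")


def parse_depth(raw: str | float | None) -> DepthObservation:
    """Parse a depth string into a :class:`DepthObservation`.

    Total: every input maps to exactly one observation.  A single number is
    an exact depth; two numbers (separated by a hyphen, en-dash, slash, ...)
    collapse to the midpoint of their extremes, flagged ``range_midpoint``;
    anything without a number is ``missing``.  Trailing prime marks and "?"
    (which flags the result uncertain) are stripped before parsing.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        raw = ""
    text = str(raw).strip()
    uncertain = "?" in text
    numbers = [float(m) for m in _NUMBER_RE.findall(text)]
    if not numbers:
        if text not in ("", "-", "–", "—"):
            logger.warning("unparsable depth %r treated as missing", text)
        return DepthObservation(None, "missing", str(raw), uncertain)
    if len(numbers) == 1:
        value, kind = numbers[0], "exact"
    else:
        if len(numbers) > 2:
            logger.warning("depth %r has >2 numbers; using extremes", text)
        value, kind = (min(numbers) + max(numbers)) / 2.0, "range_midpoint"
    if value <= 0:
        logger.warning("non-positive depth %r treated as missing", text)
        return DepthObservation(None, "missing", str(raw), uncertain)
    return DepthObservation(value, kind, str(raw), uncertain)


# --------------------------------------------------------------------------
# Specimens
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenRecord:
    """One collected colony with its identification and collection metadata.

    ``id_status`` is ``identified`` when the colony was examined
    morphologically and assigned a (possibly provisional) morphotype, else
    ``unidentified``; unidentified colonies never enter the resolved-species
    denominator.
    """

    specimen_id: str
    species: str
    genus: str
    id_status: str  # 'identified' | 'unidentified'
    site: str
    region: str
    depth: DepthObservation
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.id_status not in ("identified", "unidentified"):
            raise ValueError(f"bad id_status: {self.id_status!r}")


def read_specimen_table(
    path: str | Path,
) -> tuple[list[SpecimenRecord], pd.DataFrame | None]:
    """Read a specimen metadata TSV.

    Returns the specimen records plus, when the table carries extra
    (non-reserved) columns, a DataFrame of integer haplotype codes indexed
    by specimen_id with one column per marker; ``None`` otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"specimen table missing required column {col!r}")
    ids = df["specimen_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise DataError(f"duplicate specimen_id(s): {', '.join(dupes)}")

    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                species=row["species"],
                genus=row["genus"],
                id_status=row["id_status"],
                site=row["site"],
                region=row["region"],
                depth=parse_depth(row["depth"]),
                lat=float(row["lat"]) if row.get("lat", "") not in ("", None) else None,
                lon=float(row["lon"]) if row.get("lon", "") not in ("", None) else None,
            )
        )

    marker_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    codes: pd.DataFrame | None = None
    if marker_cols:
        try:
            codes = df.set_index("specimen_id")[marker_cols].astype(int)
        except ValueError as exc:
            raise FormatError(f"non-integer haplotype code: {exc}") from exc
    return records, codes


def specimens_by_id(specimens: Iterable[SpecimenRecord]) -> dict[str, SpecimenRecord]:
    out = {s.specimen_id: s for s in specimens}
    return out


# --------------------------------------------------------------------------
# Alignments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskInterval:
    """A 1-based inclusive column interval to exclude from analysis."""

    start: int
    end: int
    reason: str = "unalignable"  # 'unalignable' | 'ambiguous' | 'trim'

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad mask interval {self.start}-{self.end}")
        if self.reason not in ("unalignable", "ambiguous", "trim"):
            raise ValueError(f"bad mask reason: {self.reason!r}")


@dataclass(frozen=True)
class AlignedMarkerSet:
    """One marker's aligned sequences, uppercase, over {A,C,G,T,-,IUPAC}.

    ``masks`` are column intervals scheduled for removal by
    :func:`hapresolve.haplotypes.apply_masks`; an alignment fresh from
    that function has none left.
    """

    marker: str
    sequences: Mapping[str, str]
    length: int
    masks: tuple[MaskInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if len(seq) != self.length:
                raise FormatError(
                    f"{self.marker}: sequence {sid!r} has length {len(seq)}, "
                    f"expected {self.length}"
                )
        for m in self.masks:
            if m.end > self.length:
                raise ValueError(
                    f"{self.marker}: mask {m.start}-{m.end} exceeds length {self.length}"
                )

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def subset(self, ids: Iterable[str]) -> "AlignedMarkerSet":
        keep = [i for i in self.specimen_ids if i in set(ids)]
        return replace(self, sequences={i: self.sequences[i] for i in keep})


def read_marker_alignment(
    path: str | Path,
    marker: str,
    masks: Iterable[MaskInterval] = (),
) -> AlignedMarkerSet:
    """Read one marker's FASTA alignment.

    Record IDs are truncated at the first whitespace to match specimen IDs.
    Sequences are uppercased and validated against the DNA alphabet
    (gaps and IUPAC ambiguity codes allowed, U rejected); all must share
    one length.
    """
    sequences: dict[str, str] = {}
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id.split()[0]
        if sid in sequences:
            raise DataError(f"{marker}: duplicate FASTA record {sid!r}")
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise FormatError(
                    f"{marker}: record {sid!r} has invalid character "
                    f"{ch!r} at column {pos}"
                )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FormatError(
                f"{marker}: ragged alignment — record {sid!r} has length "
                f"{len(seq)}, expected {length}"
            )
        sequences[sid] = seq
    if length is None:
        raise FormatError(f"{marker}: empty FASTA {path}")
    return AlignedMarkerSet(marker=marker, sequences=sequences, length=length,
                            masks=tuple(masks))


def write_marker_alignment(alignment: AlignedMarkerSet, path: str | Path) -> None:
    """Write an alignment as plain FASTA (wrapped at 70 columns)."""
    with open(path, "w") as fh:
        for sid, seq in alignment.sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# --------------------------------------------------------------------------
# Report writing
# --------------------------------------------------------------------------

def write_reports(
    outdir: str | Path,
    specimens: list[SpecimenRecord],
    assignments: Mapping[str, "object"],
    combination: "object",
    report: "object",
    distance_summaries: Mapping[str, "object"] | None = None,
    ranges: list | None = None,
    occupancy: "object" | None = None,
) -> dict[str, Path]:
    """Write the analysis outputs: per-specimen haplotype table (TSV),
    marker summary table (TSV), and a machine-readable JSON mirror.

    Deterministic: identical inputs produce byte-identical files.
    Returns a name → path map of everything written.
    """
    if not specimens:
        raise DataError("refusing to write reports for an empty dataset")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # (a) per-specimen haplotype table
    markers = list(assignments)
    rows = []
    for s in specimens:
        row = {
            "specimen_id": s.specimen_id,
            "species": s.species,
            "genus": s.genus,
            "id_status": s.id_status,
            "site": s.site,
            "region": s.region,
            "depth": s.depth.raw,
        }
        for m in markers:
            row[m] = assignments[m].labels.get(s.specimen_id, "")
        if combination is not None:
            row["combination"] = combination.labels.get(s.specimen_id, "")
        rows.append(row)
    hap_path = outdir / "haplotype_table.tsv"
    pd.DataFrame(rows).to_csv(hap_path, sep="\t", index=False)
    written["haplotype_table"] = hap_path

    # (b) marker summary table (one column per marker subset)
    summary_df = report.to_frame()
    if distance_summaries:
        dist_rows = {
            "intraspecific_p_range": {},
            "intraspecific_bp_range": {},
            "interspecific_p_range": {},
            "interspecific_bp_range": {},
            "intergeneric_p_range": {},
            "intergeneric_bp_range": {},
        }
        for name, summ in distance_summaries.items():
            for level in ("intraspecific", "interspecific", "intergeneric"):
                stats = summ.levels.get(level)
                if stats is None:
                    dist_rows[f"{level}_p_range"][name] = "absent"
                    dist_rows[f"{level}_bp_range"][name] = "absent"
                else:
                    dist_rows[f"{level}_p_range"][name] = (
                        f"{100 * stats.min_p:.2f}%-{100 * stats.max_p:.2f}%"
                    )
                    dist_rows[f"{level}_bp_range"][name] = (
                        f"{stats.min_bp}-{stats.max_bp}"
                    )
        summary_df = pd.concat([summary_df, pd.DataFrame(dist_rows).T])
    summary_path = outdir / "marker_summary.tsv"
    summary_df.to_csv(summary_path, sep="\t")
    written["marker_summary"] = summary_path

    # (c) machine-readable mirror
    payload: dict = {"resolution": report.to_dict()}
    if distance_summaries:
        payload["distances"] = {
            name: summ.to_dict() for name, summ in distance_summaries.items()
        }
    if ranges is not None:
        payload["haplotype_ranges"] = [r.to_dict() for r in ranges]
    if occupancy is not None:
        occ_path = outdir / "depth_occupancy.tsv"
        occupancy.to_frame().to_csv(occ_path, sep="\t")
        written["depth_occupancy"] = occ_path
        payload["depth_occupancy"] = {
            "bin_width_m": occupancy.bin_width,
            "total_placed": int(occupancy.to_frame().to_numpy().sum()),
        }
    json_path = outdir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["report_json"] = json_path
    return written
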