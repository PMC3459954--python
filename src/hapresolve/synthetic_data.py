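"""Synthetic multi-marker datasets with species-level haplotype structure.

The generator emulates the statistical shape of a multi-marker barcoding
survey of congeneric morphospecies plus outgroup genera: genus backbones a
handful of substitutions apart, congeneric species separated by 1–12
substitutions per marker, 1–4 intraspecific substitutions between variants
of one species, optional verbatim haplotype sharing across congeners (an
incomplete-lineage-sorting phenocopy that creates unresolvable species),
clade-specific indel blocks, and optional ambiguity injection.  Every draw
passes through one seeded generator, so output is byte-reproducible.

Also exposes the packaged reference dataset: per-specimen haplotype codes
for 54 North Pacific primnoid octocoral colonies (39 *Narella* plus 15
colonies of five other genera) across the five mitochondrial markers
NCR1, ND6, ND2, COI+ and MutS, with collection site, region and depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AlignedMarkerSet,
    SpecimenRecord,
    parse_depth,
    read_specimen_table,
    write_marker_alignment,
)

_BASES = np.array(list("ACGT"))

DEFAULT_MARKER_LENGTHS = {
    "NCR1": 306,
    "ND6": 606,
    "ND2": 775,
    "COI+": 877,
    "MutS": 854,
}

#: Default site pool (name, region, lat, lon): a Gulf-of-Alaska-like chain,
#: an Aleutian seamount, and a Hawaiian-like chain, so regional structure
#: and great-circle spans are exercised.
DEFAULT_SITES = (
    ("SiteA", "North", 56.0, -145.0),
    ("SiteB", "North", 54.5, -140.0),
    ("SiteC", "North", 53.0, -135.5),
    ("SiteD", "West", 52.5, 170.0),
    ("SiteE", "South", 25.5, -171.0),
    ("SiteF", "South", 23.0, -166.0),
    ("SiteG", "South", 19.5, -156.1),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``indel_blocks`` lists (marker, start, end, genus_index) column
    intervals (1-based inclusive) gapped out in every member of that genus.
    ``share_prob`` is the per-species probability of inheriting its base
    haplotype verbatim from a congener, across all markers at once.

    The per-marker intraspecific draw is capped at
    ``max(1, floor(intra_ceiling * length))``: intraspecific variants stay
    below the cryptic-species divergence criterion wherever marker length
    permits, matching the structure of real multi-marker surveys in which
    1–4 within-species substitutions occur only on the longer markers.
    (On markers shorter than 1/intra_ceiling columns the one mandatory
    difference may still exceed the criterion.)
    """

    n_genera: int = 3
    species_per_genus: int = 4
    specimens_per_species: tuple[int, int] = (2, 5)
    marker_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS)
    )
    inter_genus_diffs: int = 8
    inter_species_diffs: tuple[int, int] = (1, 12)
    intra_species_diffs: tuple[int, int] = (1, 4)
    intra_ceiling: float = 0.005
    variants_per_species: tuple[int, int] = (1, 2)
    share_prob: float = 0.0
    indel_blocks: tuple[tuple[str, int, int, int], ...] = ()
    ambig_prob: float = 0.0
    depth_range_m: tuple[float, float] = (400.0, 4600.0)
    depth_band_width_m: float = 400.0
    sites: tuple[tuple[str, str, float, float], ...] = DEFAULT_SITES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.share_prob <= 1.0):
            raise ValueError("share_prob must be in [0, 1]")
        if not (0.0 <= self.ambig_prob <= 1.0):
            raise ValueError("ambig_prob must be in [0, 1]")
        if min(self.marker_lengths.values(), default=1) <= 0:
            raise ValueError("marker lengths must be positive")
        for lo, hi in (
            self.specimens_per_species,
            self.inter_species_diffs,
            self.intra_species_diffs,
            self.variants_per_species,
        ):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth emitted alongside a synthetic dataset.

    ``marker_class`` numbers the distinct CLEAN (pre-indel, pre-ambiguity)
    sequences per marker by first occurrence; ``planted_diffs`` gives the
    clean differing-site count per within-species specimen pair per marker;
    ``shared_species`` are the species that copied a congener's haplotype,
    with ``shared_pairs`` naming (copier, donor).
    """

    species_of: Mapping[str, str]
    marker_class: Mapping[str, Mapping[str, int]]
    clean_sequences: Mapping[str, Mapping[str, str]]
    planted_diffs: Mapping[tuple[str, str], Mapping[str, int]]
    shared_species: frozenset[str]
    shared_pairs: tuple[tuple[str, str], ...]

    def n_classes(self, marker: str) -> int:
        return len(set(self.marker_class[marker].values()))


class InfeasibleConfig(ValueError):
    """The requested number of distinct sequences cannot be realized."""


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return out


def _draw_int(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def generate(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[dict[str, AlignedMarkerSet], list[SpecimenRecord], TruthRecord]:
    """Generate aligned markers, specimen metadata, and ground truth.

    Deterministic given ``config.seed``.  When ``outdir`` is given, the
    alignments (one FASTA per marker) and the specimen table (TSV) are
    also written there in the formats ``core_io`` reads back.
    """
    rng = np.random.default_rng(config.seed)
    markers = list(config.marker_lengths)
    if not markers:
        raise InfeasibleConfig("at least one marker is required")

    # Species plan: genus 1 is the focal genus; species within a genus may
    # share the base haplotype of an earlier congener.
    species_plan: list[tuple[str, str, str | None]] = []  # (species, genus, donor)
    for g in range(config.n_genera):
        genus = f"Genus{g + 1}"
        congeners: list[str] = []
        for s in range(config.species_per_genus):
            name = f"{genus} sp{s + 1}"
            donor = None
            if congeners and rng.random() < config.share_prob:
                donor = congeners[int(rng.integers(len(congeners)))]
            species_plan.append((name, genus, donor))
            congeners.append(name)

    # Backbones and species base sequences per marker (clean: no indels).
    base_seqs: dict[str, dict[str, np.ndarray]] = {m: {} for m in markers}
    seen_concat: set[tuple] = set()
    roots = {
        m: _BASES[rng.integers(4, size=config.marker_lengths[m])] for m in markers
    }
    genus_backbone: dict[str, dict[str, np.ndarray]] = {m: {} for m in markers}
    for g in range(config.n_genera):
        genus = f"Genus{g + 1}"
        for m in markers:
            L = config.marker_lengths[m]
            k = min(config.inter_genus_diffs, L)
            pos = rng.choice(L, size=k, replace=False)
            genus_backbone[m][genus] = _mutate(roots[m], pos, rng)

    for name, genus, donor in species_plan:
        if donor is not None:
            for m in markers:
                base_seqs[m][name] = base_seqs[m][donor].copy()
            continue
        for _ in range(50):
            candidate = {}
            for m in markers:
                L = config.marker_lengths[m]
                k = min(_draw_int(rng, config.inter_species_diffs), L)
                pos = rng.choice(L, size=k, replace=False) if k else np.array([], int)
                candidate[m] = _mutate(genus_backbone[m][genus], pos, rng)
            key = tuple("".join(candidate[m]) for m in markers)
            if key not in seen_concat:
                seen_concat.add(key)
                for m in markers:
                    base_seqs[m][name] = candidate[m]
                break
        else:
            raise InfeasibleConfig(
                f"could not draw a distinct sequence for {name}; "
                "sequence space too constrained"
            )

    # Variants and specimens.
    clean: dict[str, dict[str, str]] = {m: {} for m in markers}
    species_of: dict[str, str] = {}
    records: list[SpecimenRecord] = []
    site_pool = list(config.sites)
    lo_d, hi_d = config.depth_range_m
    half = config.depth_band_width_m / 2.0
    specimen_counter = 0
    for name, genus, donor in species_plan:
        n_spec = _draw_int(rng, config.specimens_per_species)
        if n_spec == 0:
            continue
        n_var = min(_draw_int(rng, config.variants_per_species), n_spec)
        variants: list[dict[str, np.ndarray]] = [
            {m: base_seqs[m][name] for m in markers}
        ]
        for _ in range(n_var - 1):
            for _try in range(50):
                var = {}
                for m in markers:
                    L = config.marker_lengths[m]
                    cap = max(1, int(config.intra_ceiling * L))
                    k = min(_draw_int(rng, config.intra_species_diffs), cap, L)
                    pos = rng.choice(L, size=k, replace=False) if k else np.array([], int)
                    var[m] = _mutate(base_seqs[m][name], pos, rng)
                key = tuple("".join(var[m]) for m in markers)
                if key not in seen_concat:
                    seen_concat.add(key)
                    variants.append(var)
                    break
            else:
                raise InfeasibleConfig(f"could not draw a distinct variant for {name}")
        center = rng.uniform(lo_d + half, hi_d - half)
        n_sites = int(rng.integers(1, min(2, len(site_pool)) + 1))
        sp_sites = [site_pool[i] for i in rng.choice(len(site_pool), n_sites, replace=False)]
        for i in range(n_spec):
            specimen_counter += 1
            sid = f"S{specimen_counter:04d}"
            var = variants[i % len(variants)]
            for m in markers:
                clean[m][sid] = "".join(var[m])
            species_of[sid] = name
            site, region, lat, lon = sp_sites[int(rng.integers(len(sp_sites)))]
            depth = center + rng.uniform(-half, half)
            records.append(
                SpecimenRecord(
                    specimen_id=sid, species=name, genus=genus,
                    id_status="identified", site=site, region=region,
                    depth=parse_depth(f"{depth:.1f}"), lat=lat, lon=lon,
                )
            )

    # Truth: class numbering over clean sequences, planted pairwise diffs.
    marker_class: dict[str, dict[str, int]] = {}
    for m in markers:
        codes: dict[str, int] = {}
        labels = {}
        for sid, seq in clean[m].items():
            if seq not in codes:
                codes[seq] = len(codes) + 1
            labels[sid] = codes[seq]
        marker_class[m] = labels
    planted: dict[tuple[str, str], dict[str, int]] = {}
    by_species: dict[str, list[str]] = {}
    for sid, sp in species_of.items():
        by_species.setdefault(sp, []).append(sid)
    for sp, sids in by_species.items():
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                a, b = sids[i], sids[j]
                planted[(a, b)] = {
                    m: sum(x != y for x, y in zip(clean[m][a], clean[m][b]))
                    for m in markers
                }
    shared = frozenset(sp for sp, _, d in species_plan if d is not None and sp in by_species)
    shared_pairs = tuple(
        (sp, d) for sp, _, d in species_plan if d is not None and sp in by_species
    )

    # Observed alignments: clean sequences + indel blocks + ambiguity.
    observed: dict[str, dict[str, list[str]]] = {
        m: {sid: list(seq) for sid, seq in clean[m].items()} for m in markers
    }
    genus_of = {sid: next(g for n, g, _ in species_plan if n == species_of[sid])
                for sid in species_of}
    for marker, start, end, genus_index in config.indel_blocks:
        if marker not in markers:
            raise ValueError(f"indel block names unknown marker {marker!r}")
        L = config.marker_lengths[marker]
        if not (1 <= start <= end <= L):
            raise ValueError(f"indel block {start}-{end} out of bounds for {marker}")
        target = f"Genus{genus_index + 1}"
        for sid in observed[marker]:
            if genus_of[sid] == target:
                for c in range(start - 1, end):
                    observed[marker][sid][c] = "-"
    if config.ambig_prob > 0:
        for m in markers:
            sids = list(observed[m])
            for col in range(config.marker_lengths[m]):
                if rng.random() < config.ambig_prob:
                    sid = sids[int(rng.integers(len(sids)))]
                    if observed[m][sid][col] != "-":
                        observed[m][sid][col] = "N"

    alignments = {
        m: AlignedMarkerSet(
            marker=m,
            sequences={sid: "".join(chars) for sid, chars in observed[m].items()},
            length=config.marker_lengths[m],
        )
        for m in markers
    }
    truth = TruthRecord(
        species_of=species_of,
        marker_class=marker_class,
        clean_sequences={m: dict(clean[m]) for m in markers},
        planted_diffs=planted,
        shared_species=shared,
        shared_pairs=shared_pairs,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for m in markers:
            safe = m.replace("+", "plus")
            write_marker_alignment(alignments[m], outdir / f"{safe}.fasta")
        rows = [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "id_status": r.id_status,
                "site": r.site,
                "region": r.region,
                "lat": r.lat,
                "lon": r.lon,
                "depth": r.depth.raw,
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(outdir / "specimens.tsv", sep="\t", index=False)
    return alignments, records, truth


def study_like_config(seed: int = 0, share_prob: float = 0.25) -> SimConfig:
    """A configuration shaped like the motivating survey: one focal genus
    of 12 species plus outgroup genera, five markers, haplotype sharing."""
    return SimConfig(
        n_genera=3,
        species_per_genus=12,
        specimens_per_species=(1, 5),
        share_prob=share_prob,
        seed=seed,
    )


def reference_dataset() -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """The packaged reference dataset of 54 North Pacific primnoid colonies.

    Returns the specimen records and a 54 x 5 integer code table (columns
    NCR1, ND6, ND2, COI+, MutS) giving each colony's haplotype number per
    marker.  Colonies flagged as never examined morphologically carry
    ``id_status='unidentified'``; the one colony whose identification was
    revised on re-examination carries its final morphotype label.
    """
    path = resources.files("hapresolve").joinpath("data/north_pacific_primnoids.tsv")
    with resources.as_file(path) as p:
        return read_specimen_table(p)
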