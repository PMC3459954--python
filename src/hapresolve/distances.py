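"""Uncorrected p-distances and level-wise range summaries.

p-distance = proportion of differing sites among the columns where both
sequences carry an unambiguous base, i.e. pairwise deletion of gaps and
IUPAC ambiguity codes.  Note the asymmetry with haplotype identity: a gap
difference SEPARATES haplotypes but is EXCLUDED from distances — both
conventions follow standard practice for these markers.

Distances are summarized as min–max ranges (of the proportion and of the
raw differing-site count) at three taxonomic levels: intraspecific,
interspecific within a genus, and intergeneric.  Intraspecific maxima feed
the cryptic-species screen: divergence above 0.5% within a morphospecies
is conventionally taken as suggestive of unrecognized species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import AlignedMarkerSet, SpecimenRecord

logger = logging.getLogger("hapresolve")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default intraspecific divergence above which a cryptic species is flagged.
CRYPTIC_THRESHOLD = 0.005


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def p_distance(a: str, b: str) -> tuple[float, int, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(p, diffs, compared)`` where ``compared`` counts columns in
    which both sequences have an unambiguous base (A/C/G/T), ``diffs``
    counts those that differ, and ``p = diffs / compared`` (0 with a
    warning when nothing is comparable).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    xa, xb = _to_array(a.upper()), _to_array(b.upper())
    valid = np.isin(xa, _BASE_BYTES) & np.isin(xb, _BASE_BYTES)
    compared = int(valid.sum())
    if compared == 0:
        logger.warning("no comparable columns between sequences; p set to 0")
        return 0.0, 0, 0
    diffs = int((xa[valid] != xb[valid]).sum())
    return diffs / compared, diffs, compared


@dataclass(frozen=True)
class PairwiseDistances:
    """Symmetric pairwise p-distances and differing-site counts."""

    ids: tuple[str, ...]
    p: np.ndarray  # (n, n) float
    diffs: np.ndarray  # (n, n) int
    compared: np.ndarray  # (n, n) int
    analyzed_length: int

    def pair(self, a: str, b: str) -> tuple[float, int]:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.p[i, j]), int(self.diffs[i, j])


def pairwise_matrix(alignment: AlignedMarkerSet) -> PairwiseDistances:
    """All-pairs uncorrected p-distances for one (masked) alignment."""
    ids = alignment.specimen_ids
    n = len(ids)
    if n < 2:
        raise ValueError("pairwise_matrix needs at least 2 sequences")
    mat = np.vstack([_to_array(alignment.sequences[i]) for i in ids])
    valid = np.isin(mat, _BASE_BYTES)
    p = np.zeros((n, n))
    diffs = np.zeros((n, n), dtype=int)
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        c = both.sum(axis=1)
        diffs[i, i + 1 :] = d
        compared[i, i + 1 :] = c
        with np.errstate(invalid="ignore"):
            pi = np.where(c > 0, d / np.maximum(c, 1), 0.0)
        p[i, i + 1 :] = pi
    p += p.T
    diffs += diffs.T
    compared += compared.T
    np.fill_diagonal(compared, valid.sum(axis=1))
    return PairwiseDistances(
        ids=ids, p=p, diffs=diffs, compared=compared,
        analyzed_length=alignment.length,
    )


LEVELS = ("intraspecific", "interspecific", "intergeneric")


@dataclass(frozen=True)
class LevelStats:
    min_p: float
    max_p: float
    min_bp: int
    max_bp: int
    n_pairs: int


@dataclass(frozen=True)
class DistanceSummary:
    """Min/max p-distance and base-change counts per taxonomic level.

    A level with no eligible pairs is absent from ``levels`` (not zero).
    ``per_species_max`` holds each species' maximum intraspecific
    p-distance, used by the cryptic-species screen.
    """

    marker: str
    analyzed_length: int
    levels: Mapping[str, LevelStats]
    per_species_max: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "analyzed_length": self.analyzed_length,
            "levels": {
                name: {
                    "min_p": st.min_p,
                    "max_p": st.max_p,
                    "min_bp": st.min_bp,
                    "max_bp": st.max_bp,
                    "n_pairs": st.n_pairs,
                }
                for name, st in sorted(self.levels.items())
            },
            "per_species_max_p": dict(sorted(self.per_species_max.items())),
        }


def level_summary(
    matrix: PairwiseDistances,
    specimens: Sequence[SpecimenRecord],
    focal_genus: str | None = None,
    marker: str = "",
) -> DistanceSummary:
    """Classify specimen pairs by taxonomic level and summarize ranges.

    Same species → intraspecific; same genus, different species →
    interspecific; different genus → intergeneric.  Unidentified specimens
    are excluded.  ``focal_genus`` restricts the intraspecific and
    interspecific levels to that genus (intergeneric always crosses genera).
    """
    by_id = {s.specimen_id: s for s in specimens}
    idx = [
        (k, by_id[sid]) for k, sid in enumerate(matrix.ids)
        if sid in by_id and by_id[sid].id_status == "identified"
    ]
    buckets: dict[str, list[tuple[float, int]]] = {lv: [] for lv in LEVELS}
    per_species: dict[str, float] = {}
    for a in range(len(idx)):
        ka, sa = idx[a]
        for b in range(a + 1, len(idx)):
            kb, sb = idx[b]
            pv = float(matrix.p[ka, kb])
            dv = int(matrix.diffs[ka, kb])
            if sa.genus != sb.genus:
                buckets["intergeneric"].append((pv, dv))
            elif focal_genus is not None and sa.genus != focal_genus:
                continue
            elif sa.species == sb.species:
                buckets["intraspecific"].append((pv, dv))
                if pv > per_species.get(sa.species, -1.0):
                    per_species[sa.species] = pv
            else:
                buckets["interspecific"].append((pv, dv))
    levels = {}
    for name, pairs in buckets.items():
        if not pairs:
            continue
        ps = [p for p, _ in pairs]
        ds = [d for _, d in pairs]
        levels[name] = LevelStats(
            min_p=min(ps), max_p=max(ps), min_bp=min(ds), max_bp=max(ds),
            n_pairs=len(pairs),
        )
    return DistanceSummary(
        marker=marker, analyzed_length=matrix.analyzed_length,
        levels=levels, per_species_max=per_species,
    )


def flag_cryptic(
    summary: DistanceSummary, threshold: float = CRYPTIC_THRESHOLD
) -> list[str]:
    """Species whose maximum intraspecific p-distance exceeds the cutoff.

    Strict inequality: a species at exactly the threshold is not flagged.
    """
    return sorted(
        sp for sp, mx in summary.per_species_max.items() if mx > threshold
    )
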