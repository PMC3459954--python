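import pytest

import hapresolve as hr

MARKERS = ("NCR1", "ND6", "ND2", "COI+", "MutS")


@pytest.fixture(scope="session")
def reference():
    """Packaged reference dataset: 54 specimen records + 54x5 code table."""
    return hr.reference_dataset()


@pytest.fixture(scope="session")
def reference_assignments(reference):
    """Single-marker haplotype assignments built from the code table."""
    _, codes = reference
    return {
        m: hr.combination_from_codes(codes[[m]], marker_set=(m,))
        for m in codes.columns
    }


@pytest.fixture(scope="session")
def small_synthetic():
    """A small clean synthetic dataset (no sharing, indels, or ambiguity)."""
    config = hr.SimConfig(
        n_genera=2,
        species_per_genus=4,
        specimens_per_species=(2, 4),
        marker_lengths={"mA": 180, "mB": 220},
        variants_per_species=(1, 2),
        seed=7,
    )
    return config, hr.generate(config)


def make_alignment(seqs, marker="m", masks=()):
    """Build an AlignedMarkerSet from a list or dict of equal-length strings."""
    if not isinstance(seqs, dict):
        seqs = {f"s{i + 1}": s for i, s in enumerate(seqs)}
    length = len(next(iter(seqs.values()), ""))
    return hr.AlignedMarkerSet(
        marker=marker, sequences=seqs, length=length, masks=tuple(masks)
    )
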