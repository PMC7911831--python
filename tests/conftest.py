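"""Shared fixtures: synthetic lysogens and the published annotation table."""

from pathlib import Path

import pytest

from haloprov.seqio import GenomeRecord, read_features_tsv
from haloprov.synthetic import build_lysogen

DATA = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def hardycor1_features():
    """CDS coordinate table of halovirus Hardycor1 (GenBank MT152698)."""
    return read_features_tsv(DATA / "MT152698_features.tsv")


@pytest.fixture(scope="session")
def hardycor1_coords(hardycor1_features):
    """Placeholder record carrying the published coordinates (45,142 bp,
    circular); the sequence itself is not distributed with the package."""
    return GenomeRecord(
        id="MT152698",
        seq="A" * 45142,
        topology="circular",
        features=hardycor1_features,
    )


@pytest.fixture(scope="session")
def lysogen_bundle():
    """One deterministic synthetic lysogen: (lysogen, element, truth)."""
    return build_lysogen(host_length=15000, element_length=5000, att_len=13, seed=11)
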