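import pytest

from barcodeforest import (
    BarcodeRecord,
    ForestConfig,
    ReferenceLibrary,
    SimulationParams,
    generate_library,
    write_fasta,
)


@pytest.fixture
def tiny_library():
    """Three species, three hand-written records each, clearly distinct."""
    records = []
    seqs = {
        "Fusarium oxysporum": "ACGTACGTACGTACGTACGT",
        "Aspergillus niger": "TTTTGGGGCCCCAAAATTTT",
        "Penicillium chrysogenum": "GACGACGACGACGACGACGA",
    }
    for sp, seq in seqs.items():
        for j in range(3):
            records.append(BarcodeRecord(f"{sp.split()[0][:3].upper()}{j}", sp, seq))
    return ReferenceLibrary(records)


@pytest.fixture
def separable_library():
    """Zero within-species noise: identical sequences within species,
    independent random ancestors across species."""
    return generate_library(
        SimulationParams(n_species=5, seqs_per_species=4, length=200,
                         within_sub_rate=0.0, seed=42)
    )


@pytest.fixture
def noisy_library():
    """Well-separated species with mild within-species variation."""
    return generate_library(
        SimulationParams(n_species=8, seqs_per_species=4, length=300,
                         within_sub_rate=0.02, seed=7)
    )


@pytest.fixture
def fast_config():
    return ForestConfig(ntree=60, seed=5)


@pytest.fixture
def reference_fasta(tmp_path, noisy_library):
    path = tmp_path / "reference.fasta"
    write_fasta(noisy_library, path)
    return path
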