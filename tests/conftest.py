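import pytest

from exomir.synthetic_data import ReadSimDesign, generate_reference


@pytest.fixture(scope="session")
def bundle():
    """Shared small reference bundle (precursors, contaminants, genome, loci)."""
    return generate_reference(12, 8, 8000, seed=11, n_novel_loci=2, n_other_species=1)


@pytest.fixture()
def small_design():
    samples = {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B", "B3": "B"}
    return ReadSimDesign(samples=samples, reads_per_sample=400, seed=7)
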