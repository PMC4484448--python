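import pandas as pd
import pytest

from spectracount import SimulationConfig, generate_truth, simulate_psm_table


def make_psms(rows):
    """Build a PSM DataFrame from (spectrum_id, peptide, protein, score,
    threshold, is_decoy, sample) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id",
            "peptide",
            "protein",
            "score",
            "identity_threshold",
            "is_decoy",
            "sample",
        ],
    )


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled study for fast structural tests."""
    return SimulationConfig(
        n_proteins=150,
        total_spectra_per_sample=1200,
        frac_differential=0.3,
        module_size=12,
        decoy_fraction=0.05,
        n_generic_categories=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_psms(small_truth, small_config):
    return simulate_psm_table(small_truth, small_config)
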