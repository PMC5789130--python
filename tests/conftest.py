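import pytest

from adrsignal import synthetic
from adrsignal.reports import CaseReport


@pytest.fixture
def two_drug_report() -> CaseReport:
    return CaseReport(report_id="r1", year=2010, drugs=("A", "B"), adrs=("X",))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic SRS database shared across tests (read-only)."""
    cfg = synthetic.SimConfig(
        n_reports=2000,
        n_drugs=60,
        n_adrs=20,
        n_causal_pairs=8,
        n_clusters=15,
        background_adr_rate=0.01,
        seed=42,
    )
    reports, truth = synthetic.generate_reports(cfg)
    return cfg, reports, truth
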