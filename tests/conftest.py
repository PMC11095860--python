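import numpy as np
import pytest

from icipair.lineage import EventCatalog, EventKey


@pytest.fixture
def rng():
    return np.random.default_rng(20240111)


@pytest.fixture
def small_catalog():
    return EventCatalog(
        cohort_size=10,
        freq={
            EventKey("STK11", "indel", "p.K78fs"): 0.1,
            EventKey("B2M", "SNV", "p.E94*"): 0.2,
            EventKey("KRAS", "SNV", "p.G12C"): 0.3,
            EventKey("TP53", "SNV", "p.R273H"): 0.5,
            EventKey("KEAP1", "CNA", "loss"): 1.0,
        },
    )


def random_catalog_and_samples(rng, n_events=8, cohort_size=20):
    """Random small catalog plus two event sets drawn from it (oracle
    fodder for similarity-score equivalence tests)."""
    genes = ["G%d" % i for i in range(n_events)]
    events = [EventKey(g, "SNV", f"p.A{i}T") for i, g in enumerate(genes)]
    freq = {e: float(rng.integers(1, cohort_size + 1)) / cohort_size for e in events}
    catalog = EventCatalog(cohort_size=cohort_size, freq=freq)
    a = {e for e in events if rng.random() < 0.5}
    b = {e for e in events if rng.random() < 0.5}
    return catalog, a, b
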