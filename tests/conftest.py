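import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from apmsnet.io import ProteinDB, evidence_frame
from apmsnet.synthetic import SimulationConfig, simulate_experiment

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_db() -> ProteinDB:
    rng = np.random.default_rng(7)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = {
        "P1": "".join(rng.choice(aas, 100)),
        "P2": "".join(rng.choice(aas, 200)),
        "P3": "".join(rng.choice(aas, 300)),
        "BAIT": "".join(rng.choice(aas, 400)),
    }
    return ProteinDB(seqs)


@pytest.fixture(scope="session")
def small_sim():
    """Default-structure experiment at desk scale (shared across tests)."""
    cfg = SimulationConfig(seed=11, total_spectra_per_run=20_000, contaminant_count=40)
    return cfg, simulate_experiment(cfg)


def make_evidence(rows):
    """rows: iterable of (peptide, count, ids)."""
    return evidence_frame(rows)


def random_instance(rng: np.random.Generator):
    """Random small evidence table + matching ProteinDB (≤6 proteins, ≤10 peptides)."""
    n_prot = int(rng.integers(2, 7))
    proteins = [f"P{i}" for i in range(n_prot)]
    lengths = rng.integers(50, 500, size=n_prot)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    db = ProteinDB(
        {p: "".join(rng.choice(aas, int(l))) for p, l in zip(proteins, lengths)}
    )
    n_pep = int(rng.integers(1, 11))
    rows = []
    for j in range(n_pep):
        size = int(rng.integers(1, n_prot + 1))
        members = list(rng.choice(proteins, size=size, replace=False))
        count = int(rng.integers(0, 21))
        rows.append((f"pep{j}", count, members))
    return make_evidence(rows), db
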