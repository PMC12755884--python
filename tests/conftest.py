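"""Shared fixtures: tiny hand-built alignments and small simulated datasets.

All data are generated programmatically; the simulated fixtures are
session-scoped so the more expensive scenarios are built once.
"""
from __future__ import annotations

import numpy as np
import pytest

from hybridtrace.io_core import CellRecord, GeneAlignment
from hybridtrace.simulate import SimConfig, simulate_population


def make_alignment(gene_id, mapping, frame_offset=0) -> GeneAlignment:
    return GeneAlignment.from_sequences(gene_id, mapping, frame_offset)


@pytest.fixture
def toy_two_groups():
    """10 sequences in two groups at ~2% internal / ~15% between divergence."""
    rng = np.random.default_rng(42)
    L = 300
    bases = np.frombuffer(b"ACGT", dtype="S1")
    anc = bases[rng.integers(0, 4, L)]
    other = anc.copy()
    hit = rng.random(L) < 0.16
    other[hit] = bases[(np.searchsorted(bases, other[hit])
                        + rng.integers(1, 4, hit.sum())) % 4]
    seqs = {}
    for grp, cons, n in (("a", anc, 5), ("b", other, 5)):
        for i in range(n):
            s = cons.copy()
            h = rng.random(L) < 0.01
            s[h] = bases[(np.searchsorted(bases, s[h])
                          + rng.integers(1, 4, h.sum())) % 4]
            seqs[f"{grp}{i}"] = s.tobytes().decode()
    return make_alignment("toy", seqs)


@pytest.fixture(scope="session")
def sim_basic():
    """Two clean species, no transfers, fully observed."""
    cfg = SimConfig(n_species=2, n_genes=20, gene_length_bp=300,
                    n_cells_per_species=(20, 20),
                    completeness_mean=1.0, completeness_range=(1.0, 1.0),
                    seed=101)
    return cfg, *simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_transfers():
    """Two species with planted whole-gene transfers, SAG-sampled."""
    cfg = SimConfig(n_species=2, n_genes=50, gene_length_bp=300,
                    within_div=0.02, n_cells_per_species=(100, 100),
                    completeness_mean=0.3, whole_gene_transfer_rate=0.3,
                    seed=202)
    return cfg, *simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_blocks():
    """Low-diversity recipient with planted sub-gene transfers, fully
    observed: the planted-SNP-block benchmark."""
    cfg = SimConfig(n_species=2, n_genes=30, gene_length_bp=900,
                    backbone_frac=1.0, n_cells_per_species=(50, 30),
                    completeness_mean=1.0, completeness_range=(1.0, 1.0),
                    subgene_transfer_rate=1.5, seed=303)
    return cfg, *simulate_population(cfg)
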