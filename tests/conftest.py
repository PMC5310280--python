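import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from gaap.formats import ClusterTable


def make_cluster_table(layouts, replicon="chr") -> ClusterTable:
    """Build a ClusterTable from {genome: [(gene, start, end, strand), ...]}."""
    rows = []
    for genome, genes in layouts.items():
        for gene, start, end, strand in genes:
            rows.append((gene, genome, replicon, start, end, strand))
    return ClusterTable(
        pd.DataFrame(rows, columns=["cluster_id", "genome_id", "replicon_id", "start", "end", "strand"])
    )


def layout_from_order(order, gene_len=100, spacer=50):
    """Evenly spaced layout rows realizing a signed gene order."""
    rows, pos = [], 0
    for gene, sign in order:
        rows.append((gene, pos, pos + gene_len, "+" if sign == 1 else "-"))
        pos += gene_len + spacer
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim():
    """A small but fully featured simulated pangenome (deterministic)."""
    from gaap.simulate import SimConfig, simulate_pangenome

    cfg = SimConfig(n_refs=4, n_core=60, n_dispensable=12, n_segments=3,
                    coverage=40.0, n_breaks=14, seed=42)
    return cfg, simulate_pangenome(cfg, np.random.default_rng(42))


def random_signed_orders(rng, max_genes=10, max_genomes=5):
    """Random instance for the segment-identification oracle."""
    n = int(rng.integers(2, max_genes + 1))
    g = int(rng.integers(2, max_genomes + 1))
    genes = [f"g{i}" for i in range(n)]
    orders = []
    for _ in range(g):
        perm = rng.permutation(n)
        signs = rng.integers(0, 2, n) * 2 - 1
        orders.append([(genes[int(p)], int(s)) for p, s in zip(perm, signs)])
    return orders
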