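"""Shared fixtures: tiny hand-built panels and small simulated studies."""

import numpy as np
import pytest

from campseq.panel import AssayDefinition, AssayPanel
from campseq import simulate


def _mutate_at(seq: str, positions: list[int], shift: int = 1) -> str:
    """Substitute the base at each position by a deterministic other base."""
    order = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = order[(order.index(out[p]) + shift) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def toy_assays() -> dict[str, AssayDefinition]:
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    assays = {}
    for gene, positions in (("GENE1", [25, 30, 41, 52, 60, 75]), ("GENE2", [22, 33, 44, 55, 66, 77])):
        nt = "".join(rng.choice(bases, size=101))
        assays[gene] = AssayDefinition(
            gene_id=gene, nt_sequence=nt, is_sequence=_mutate_at(nt, positions)
        )
    return assays


@pytest.fixture(scope="session")
def toy_panel(toy_assays) -> AssayPanel:
    barcode_table = {
        ("AAAA", "TTTT"): ("S1", 1),
        ("CCCC", "GGGG"): ("S1", 2),
        ("ACAC", "TGTG"): ("S2", 1),
        ("GTGT", "CACA"): ("S2", 2),
    }
    return AssayPanel(assays=dict(toy_assays), barcode_table=barcode_table)


@pytest.fixture(scope="session")
def small_study() -> simulate.StudyData:
    """An 8-gene ERCC-style study small enough for FASTQ round trips."""
    config = simulate.ercc_config(seed=11, reads_per_library=2000, n_genes=8, error_rate=0.0)
    return simulate.simulate_study(config)


@pytest.fixture(scope="session")
def ercc_study() -> simulate.StudyData:
    """Count-level ERCC-design study at full read depth."""
    return simulate.simulate_study(simulate.ercc_config(seed=5, reads_per_library=100_000))
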