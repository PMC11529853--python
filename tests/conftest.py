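import numpy as np
import pytest

from amplicycle.coverage import CoverageProfile
from amplicycle.fragments import Fragment
from amplicycle.graph import AmpliconGraph
from amplicycle.simulate import NoiseSpec, emit_fixture, heterogeneity_truth


@pytest.fixture
def uniform_profile():
    """40x over chr1:[0, 300000)."""
    return CoverageProfile.from_intervals([("chr1", 0, 300_000, 40.0)])


@pytest.fixture
def fig1c_graph():
    """Hand-built graph of the canonical heterogeneity scenario.

    Fragments A, B, D, C laid consecutively on chr1; junction edges for the
    two rings ABC (via a deletion-type jump over D) and BD, plus spatial
    adjacencies.  Returns (graph, name->fid map).
    """
    frags = {
        "A": Fragment(0, "chr1", 1_000_000, 1_200_000, 35.0),
        "B": Fragment(1, "chr1", 1_200_000, 1_400_000, 55.0),
        "D": Fragment(2, "chr1", 1_400_000, 1_550_000, 25.0),
        "C": Fragment(3, "chr1", 1_550_000, 1_700_000, 35.0),
    }
    g = AmpliconGraph()
    for f in frags.values():
        g.add_fragment(f)
    # ring ABC: B->C jump (DEL over D), C->A circularization (DUP-type)
    g.add_junction((1, "h"), (3, "t"), "sv", 30.0, "DEL", 0)
    g.add_junction((3, "h"), (0, "t"), "sv", 30.0, "DUP", 1)
    # ring BD: D->B circularization
    g.add_junction((2, "h"), (1, "t"), "sv", 20.0, "DUP", 2)
    # spatial adjacency along the chromosome
    g.add_junction((0, "h"), (1, "t"), "spatial", 35.0, None, 3)
    g.add_junction((1, "h"), (2, "t"), "spatial", 25.0, None, 4)
    g.add_junction((2, "h"), (3, "t"), "spatial", 25.0, None, 5)
    return g, {name: f.fid for name, f in frags.items()}


@pytest.fixture
def fig1c_fixture(tmp_path):
    """Emitted zero-noise fixture of the heterogeneity truth (ABC 30x, BD
    20x, background 5x)."""
    truth = heterogeneity_truth()
    fx = emit_fixture(truth, NoiseSpec(), tmp_path, np.random.default_rng(7))
    return truth, fx
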