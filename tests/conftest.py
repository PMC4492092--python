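import numpy as np
import pytest

from kgpaths.kg import DEPENDENCY_PATH, STRUCTURED, KnowledgeGraph, Label, Triple


def make_random_graph(seed: int, n_vertices: int = 60, n_edges: int = 150, n_labels: int = 8,
                      synonym_pairs: int = 0) -> KnowledgeGraph:
    """Random multigraph used across search and feature tests."""
    rng = np.random.default_rng(seed)
    g = KnowledgeGraph()
    for _ in range(n_edges):
        a, b = rng.integers(n_vertices, size=2)
        if a == b:
            continue
        g.add_triple(
            Triple(f"N{a}", Label(DEPENDENCY_PATH, f"l{rng.integers(n_labels)}"), f"N{b}")
        )
    for _ in range(synonym_pairs):
        a, b = rng.integers(n_vertices, size=2)
        if a != b:
            g.add_triple(Triple(f"N{a}", Label(STRUCTURED, "same_as"), f"N{b}"))
    return g


@pytest.fixture
def chain_graph() -> KnowledgeGraph:
    """a - b - c with one labelled edge per hop."""
    g = KnowledgeGraph()
    g.add_triple(Triple("a", Label(STRUCTURED, "r1"), "b"))
    g.add_triple(Triple("b", Label(STRUCTURED, "r2"), "c"))
    return g


@pytest.fixture
def triangle_graph() -> KnowledgeGraph:
    g = KnowledgeGraph()
    g.add_triple(Triple("a", Label(STRUCTURED, "r1"), "b"))
    g.add_triple(Triple("b", Label(STRUCTURED, "r2"), "c"))
    g.add_triple(Triple("a", Label(STRUCTURED, "r3"), "c"))
    return g
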