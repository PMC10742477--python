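import numpy as np
import pytest

import smx


@pytest.fixture(scope="session")
def two_triangle():
    """Five vertices, six edges, two filled triangles hinged at one vertex."""
    return smx.two_triangle_complex()


@pytest.fixture(scope="session")
def two_triangle_hodge(two_triangle):
    return smx.hodge_laplacians(two_triangle)


@pytest.fixture(scope="session")
def standard_ic(two_triangle):
    """Unit mass on the first vertex, edge and triangle (labels 1; 1,2; 1,2,3)."""
    K = two_triangle
    return {
        K.find_by_labels([1]): 1.0,
        K.find_by_labels([1, 2]): 1.0,
        K.find_by_labels([1, 2, 3]): 1.0,
    }


@pytest.fixture(scope="session")
def metaplex_n5(two_triangle):
    """Coarse metaplex of the two-triangle complex (5 nodes per edge)."""
    return smx.build_metaplex(two_triangle, nodes_per_edge=5)
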