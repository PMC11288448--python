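"""Shared fixtures.

The 5-node isomorphism-free enumeration and the exact per-graph
solutions over the experiment fitness grid are expensive enough to
compute once per session; several acceptance checks (bound soundness,
balanced-formula agreement, landscape extremes) read from the same
table.
"""

from __future__ import annotations

import numpy as np
import pytest

from moranbd import families
from moranbd.enumeration import enumerate_strongly_connected
from moranbd.exact import neutral_fp_vector, solve_exact

#: fitness values exercised in the exhaustive small-graph experiments
R_GRID = (1.0, 1.1, 2.0, 25.0)


@pytest.fixture(scope="session")
def enum3():
    return enumerate_strongly_connected(3)


@pytest.fixture(scope="session")
def enum4():
    return enumerate_strongly_connected(4)


@pytest.fixture(scope="session")
def enum5():
    return enumerate_strongly_connected(5)


def solve_summary(g):
    """Structural facts and exact solutions over R_GRID for one graph."""
    nfp = neutral_fp_vector(g)
    rec = {
        "graph": g,
        "balanced": g.is_balanced(),
        "eulerian": g.is_eulerian(),
        "label": g.class_label(),
        "nfp": nfp.fp_single,
        "fp_min": nfp.fp_min,
        "by_r": {},
    }
    for r in R_GRID:
        sol = solve_exact(g, r)
        rec["by_r"][r] = {
            "fp_single": sol.fp_single,
            "ft_single": sol.ft_single,
            "t_max": sol.t_max,
            "at_max": sol.at_max,
        }
    return rec


@pytest.fixture(scope="session")
def small_tables(enum3, enum4):
    """Solved summaries for every strongly connected graph on 2-4 nodes."""
    cycle2 = enumerate_strongly_connected(2)
    out = []
    for classes in (cycle2, enum3, enum4):
        out.extend(solve_summary(cg.representative) for cg in classes)
    return out


@pytest.fixture(scope="session")
def n5_table(enum5):
    """Solved summaries for all 5048 strongly connected 5-node graphs."""
    return [solve_summary(cg.representative) | {"key": cg.canonical_key}
            for cg in enum5]


@pytest.fixture
def star4():
    return families.star(4)


@pytest.fixture
def k3():
    return families.complete(3)


def moran_fp_complete(n: int, r: float, i: int = 1) -> float:
    """Closed-form fixation probability of i mutants on the complete graph.

    Independent 1-D birth-death oracle: fp_i = (1 - r^-i) / (1 - r^-N),
    with the neutral limit i/N.
    """
    if abs(r - 1.0) < 1e-12:
        return i / n
    return (1.0 - r ** -i) / (1.0 - r ** -n)
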