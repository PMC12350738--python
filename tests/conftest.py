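"""Shared fixtures: hand-encoded hydrogen-suppressed drug graphs and an
independent per-edge brute-force oracle for every index.

The oracle deliberately avoids the package's partition/polynomial machinery:
it walks the raw edge list, computes endpoint degrees by counting, and sums
the textbook per-edge formulas with `fractions.Fraction`.  Agreement between
this oracle and both package routes is what lets printed table cells be
treated as regression goldens.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction

import pytest

from mpolykit import read_edge_list

# Hydrogen-suppressed molecular graphs, hand-encoded from the structures.
ACETAMINOPHEN_EDGES = """\
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
O7 C1
N8 C4
C9 N8
O10 C9
C11 C9
"""

METFORMIN_EDGES = """\
C1a N1
C1b N1
N1 C2
C2 N3    # C=N double bond, still one edge
C2 N4
N4 C5
C5 N6    # C=N double bond
C5 N7
"""

IBUPROFEN_EDGES = """\
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
C1 C7
C7 C8
C7 C9
C9 O10
C9 O11
C4 C12
C12 C13
C13 C14
C13 C15
"""

GABAPENTIN_EDGES = """\
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C1
C1 C7
C7 N8
C1 C9
C9 C10
C10 O11
C10 O12
"""

DRUG_EDGE_LISTS = {
    "acetaminophen": ACETAMINOPHEN_EDGES,
    "metformin": METFORMIN_EDGES,
    "ibuprofen": IBUPROFEN_EDGES,
    "gabapentin": GABAPENTIN_EDGES,
}


def parse_edges(text: str) -> list[tuple[str, str]]:
    edges = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            u, v = line.split()
            edges.append((u, v))
    return edges


def brute_force_index(edges: list[tuple[str, str]], name: str, alpha=None):
    """Sum the textbook per-edge formula straight off the edge list."""
    deg: Counter = Counter()
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    total_exact = Fraction(0)
    total_float = 0.0
    inexact = False
    for u, v in edges:
        i, j = deg[u], deg[v]
        if name == "M1":
            term = Fraction(i + j)
        elif name == "M2":
            term = Fraction(i * j)
        elif name == "mM2":
            term = Fraction(1, i * j)
        elif name == "Ralpha":
            a = Fraction(alpha if alpha is not None else Fraction(-1, 2))
            if a.denominator == 1:
                term = Fraction(i * j) ** a.numerator
            else:
                inexact = True
                total_float += float(i * j) ** float(a)
                continue
        elif name == "SDD":
            term = Fraction(i, j) + Fraction(j, i)
        elif name == "H":
            term = Fraction(2, i + j)
        elif name == "I":
            term = Fraction(i * j, i + j)
        elif name == "F":
            term = Fraction(i * i + j * j)
        elif name == "ReZG3":
            term = Fraction(i * j * (i + j))
        elif name == "AZI":
            term = Fraction(i * j, i + j - 2) ** 3
        else:
            raise KeyError(name)
        total_exact += term
    return float(total_exact) + total_float if inexact else total_exact


@pytest.fixture(scope="session")
def drug_graphs():
    return {name: read_edge_list(text, name=name)
            for name, text in DRUG_EDGE_LISTS.items()}
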