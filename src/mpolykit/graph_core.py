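"""Molecular graphs and degree-based edge partitions.

A molecule is modelled as its hydrogen-suppressed graph: heavy atoms are
vertices, bonds are edges, and bond order is discarded (a double bond is the
same edge as a single bond).  Hydrogen suppression is the caller's
responsibility — the functions here compute on the graph they are given,
verbatim.  Vertex labels are opaque strings; no element or valence semantics
are enforced.
"""

from __future__ import annotations

import csv
import io
import logging
import random
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx

from .affine import AffineCount

logger = logging.getLogger(__name__)


class GraphFormatError(ValueError):
    """Raised when an edge-list or adjacency-matrix input is malformed."""


class MolecularGraph:
    """Simple undirected graph standing for a hydrogen-suppressed molecule.

    Thin wrapper over :class:`networkx.Graph` enforcing simplicity (no
    self-loops, no parallel edges).  Disconnected graphs are allowed with a
    warning: every index computed downstream is an edge sum, so isolated
    vertices simply contribute nothing.
    """

    def __init__(self, vertices=(), edges=(), name: str = "") -> None:
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in vertices)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphFormatError(f"self-loop on vertex {u!r}")
            g.add_edge(u, v)
        self._g = g
        self.name = name
        if g.number_of_nodes() and not nx.is_connected(g):
            logger.warning("graph %s is disconnected (%d components)",
                           name or "<unnamed>", nx.number_connected_components(g))

    # -- container views -------------------------------------------------
    @property
    def nx(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_vertices == 0 or nx.is_connected(self._g)

    def __repr__(self) -> str:
        tag = f" {self.name!r}" if self.name else ""
        return f"<MolecularGraph{tag}: {self.n_vertices} vertices, {self.n_edges} edges>"


@dataclass
class EdgePartition:
    """Edge classes keyed by the ordered degree pair ``(i, j)`` with i <= j.

    Counts are :class:`AffineCount` so the same container describes both a
    concrete molecule (constant counts) and a polymer repeat-unit family
    (counts affine in the repeat parameter).
    """

    classes: dict[tuple[int, int], AffineCount] = field(default_factory=dict)
    parameter_name: str | None = None

    def __post_init__(self) -> None:
        normalized: dict[tuple[int, int], AffineCount] = {}
        for (i, j), count in self.classes.items():
            if i < 1 or j < 1:
                raise ValueError(f"degree pair ({i}, {j}) must be positive")
            key = (i, j) if i <= j else (j, i)
            count = AffineCount.coerce(count)
            normalized[key] = normalized.get(key, AffineCount()) + count
        self.classes = {k: v for k, v in sorted(normalized.items()) if not v.is_zero}

    def total(self) -> AffineCount:
        """Sum of class counts — the edge count when built from a graph."""
        out = AffineCount()
        for count in self.classes.values():
            out = out + count
        return out

    def at(self, value) -> "EdgePartition":
        """Instantiate the partition at a concrete parameter value."""
        inst = {key: AffineCount(count(value)) for key, count in self.classes.items()}
        return EdgePartition(inst)

    def __iter__(self):
        return iter(self.classes.items())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_edge_list(text: str, name: str = "") -> MolecularGraph:
    """Parse a plain-text edge list: one ``u v`` pair per line.

    ``#`` starts a comment (to end of line); blank lines are ignored.
    Duplicate lines — including reversed duplicates — collapse to one edge
    with a warning, matching the convention that a double bond is a single
    edge.  Self-loops and malformed lines are rejected with the line number.
    """
    vertices: list[str] = []
    edges: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise GraphFormatError(
                f"line {lineno}: expected 'u v', got {len(tokens)} token(s): {raw!r}"
            )
        u, v = tokens
        if u == v:
            raise GraphFormatError(f"line {lineno}: self-loop on vertex {u!r}")
        key = frozenset((u, v))
        if key in seen:
            logger.warning("line %d: duplicate edge %s-%s collapsed", lineno, u, v)
            continue
        seen.add(key)
        vertices.extend((u, v))
        edges.append((u, v))
    return MolecularGraph(vertices, edges, name=name)


def read_adjacency(text: str, name: str = "") -> MolecularGraph:
    """Parse a 0/1 adjacency matrix in CSV form.

    An optional first row of non-numeric labels names the vertices.  The
    matrix must be square and symmetric with a zero diagonal; violations are
    reported with the offending cell.
    """
    rows = [row for row in csv.reader(io.StringIO(text)) if any(c.strip() for c in row)]
    if not rows:
        raise GraphFormatError("empty adjacency input")

    def numeric(row: list[str]) -> bool:
        return all(cell.strip().lstrip("+-").isdigit() for cell in row if cell.strip())

    if numeric(rows[0]):
        labels = [f"v{k + 1}" for k in range(len(rows[0]))]
        body = rows
    else:
        labels = [cell.strip() for cell in rows[0]]
        body = rows[1:]

    n = len(labels)
    if len(body) != n or any(len(r) != n for r in body):
        raise GraphFormatError(
            f"matrix is not square: {n} column(s), {len(body)} row(s)"
        )
    matrix: list[list[int]] = []
    for r, row in enumerate(body):
        out = []
        for c, cell in enumerate(row):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise GraphFormatError(f"cell ({r + 1}, {c + 1}): expected 0 or 1, got {cell!r}")
            out.append(int(cell))
        matrix.append(out)
    for r in range(n):
        if matrix[r][r] != 0:
            raise GraphFormatError(f"nonzero diagonal at cell ({r + 1}, {r + 1})")
        for c in range(r + 1, n):
            if matrix[r][c] != matrix[c][r]:
                raise GraphFormatError(
                    f"asymmetric at cell ({r + 1}, {c + 1}): "
                    f"{matrix[r][c]} vs {matrix[c][r]}"
                )
    edges = [(labels[r], labels[c]) for r in range(n) for c in range(r + 1, n)
             if matrix[r][c]]
    return MolecularGraph(labels, edges, name=name)


# ---------------------------------------------------------------------------
# Degrees and partitions
# ---------------------------------------------------------------------------

def degree_map(g: MolecularGraph) -> dict[str, int]:
    """Vertex -> degree.  Satisfies the handshake lemma by construction."""
    return dict(g.nx.degree)


def edge_partition(g: MolecularGraph) -> EdgePartition:
    """Group edges by the unordered pair of end-vertex degrees.

    The counts |N(i,j)| returned here fully determine every degree-based
    index in this package.
    """
    deg = g.nx.degree
    classes: dict[tuple[int, int], AffineCount] = {}
    for u, v in g.nx.edges:
        i, j = sorted((deg[u], deg[v]))
        classes[(i, j)] = classes.get((i, j), AffineCount()) + 1
    return EdgePartition(classes)


def random_molecular_graph(n: int, max_degree: int = 4, seed: int = 0,
                           extra_edge_prob: float = 0.3) -> MolecularGraph:
    """Connected simple random graph with all degrees in [1, max_degree].

    Emulates the shape of hydrogen-suppressed organic molecules (max degree
    4 by default).  Grown as a random tree with degree-capped attachment,
    then sprinkled with ring-closing edges while respecting the cap.
    Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if max_degree < 1 or (n > 2 and max_degree < 2):
        raise ValueError(f"max_degree={max_degree} infeasible for a connected graph on {n} vertices")
    rng = random.Random(seed)
    labels = [f"v{k + 1}" for k in range(n)]
    deg = {v: 0 for v in labels}
    edges: list[tuple[str, str]] = []
    for k in range(1, n):
        candidates = [labels[m] for m in range(k) if deg[labels[m]] < max_degree]
        if not candidates:
            raise ValueError("degree cap too tight to keep the graph connected")
        parent = rng.choice(candidates)
        edges.append((parent, labels[k]))
        deg[parent] += 1
        deg[labels[k]] += 1
    present = {frozenset(e) for e in edges}
    # ring closures, kept sparse so random fixtures stay molecule-like
    n_extra = int(extra_edge_prob * n)
    for _ in range(n_extra):
        open_vs = [v for v in labels if deg[v] < max_degree]
        rng.shuffle(open_vs)
        placed = False
        for a_idx in range(len(open_vs)):
            for b_idx in range(a_idx + 1, len(open_vs)):
                a, b = open_vs[a_idx], open_vs[b_idx]
                if frozenset((a, b)) not in present:
                    edges.append((a, b))
                    present.add(frozenset((a, b)))
                    deg[a] += 1
                    deg[b] += 1
                    placed = True
                    break
            if placed:
                break
        if not placed:
            break
    return MolecularGraph(labels, edges, name=f"random(n={n},seed={seed})")
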