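"""Ten degree-based topological indices, computed two independent ways.

Every index here is an edge sum  sum_{(i,j)} |N(i,j)| * kernel(i, j)  over
the degree-pair partition, and equivalently the value of an operator
pipeline applied to the M-polynomial and evaluated at x = y = 1:

    name    kernel(i, j)              operator pipeline
    M1      i + j                     (Dx + Dy) M |_1          first Zagreb
    M2      i * j                     Dx Dy M |_1              second Zagreb
    mM2     1 / (i j)                 Ix Iy M |_1              modified second Zagreb
    Ralpha  (i j)^alpha               Dx^a Dy^a M |_1          general Randic
    SDD     (i^2 + j^2) / (i j)       (Dx Iy + Ix Dy) M |_1    symmetric division (deg)
    H       2 / (i + j)               2 Ix J M |_1             harmonic
    I       i j / (i + j)             Ix J Dx Dy M |_1         inverse sum indeg
    F       i^2 + j^2                 (Dx^2 + Dy^2) M |_1      forgotten
    ReZG3   i j (i + j)               Dx Dy (Dx + Dy) M |_1    redefined third Zagreb
    AZI     (i j / (i + j - 2))^3     Ix^3 Q_-2 J Dx^3 Dy^3 M |_1   augmented Zagreb

Both routes are implemented and must agree; the redundancy is the point —
it catches transcription and calculus mistakes alike.  AZI is undefined on a
(1, 1) edge (kernel denominator zero, pipeline integral divergent): that is
an error, never a silent skip.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .affine import AffineCount
from .graph_core import EdgePartition, MolecularGraph, edge_partition
from .mpoly import (MPoly, DegenerateTermError, eval_at_one, from_partition,
                    op_dx, op_dy, op_ix, op_ix_uni, op_iy, op_j, op_q)

INDEX_NAMES = ("M1", "M2", "mM2", "Ralpha", "SDD", "H", "I", "F", "ReZG3", "AZI")

#: Classic Randic exponent; any rational is accepted on the kernel route.
DEFAULT_ALPHA = Fraction(-1, 2)


class DegenerateEdgeError(ArithmeticError):
    """AZI requested for a partition containing a (1, 1) edge class."""


class UnsupportedOnThisRoute(ValueError):
    """The operator route only supports integer Randic exponents.

    Non-integer alpha would require fractional operator powers; use
    :func:`index_kernel`, where (i*j)**alpha is evaluated per edge class.
    """


def _is_integral(alpha) -> bool:
    return Fraction(alpha).denominator == 1


def kernel(name: str, i: int, j: int, alpha=None):
    """Closed-form per-edge kernel.  Exact Fraction wherever possible."""
    if name == "M1":
        return Fraction(i + j)
    if name == "M2":
        return Fraction(i * j)
    if name == "mM2":
        return Fraction(1, i * j)
    if name == "Ralpha":
        a = Fraction(DEFAULT_ALPHA if alpha is None else alpha)
        if a.denominator == 1:
            return Fraction(i * j) ** a.numerator
        return float(i * j) ** float(a)
    if name == "SDD":
        return Fraction(i * i + j * j, i * j)
    if name == "H":
        return Fraction(2, i + j)
    if name == "I":
        return Fraction(i * j, i + j)
    if name == "F":
        return Fraction(i * i + j * j)
    if name == "ReZG3":
        return Fraction(i * j * (i + j))
    if name == "AZI":
        if i + j == 2:
            raise DegenerateEdgeError(
                "AZI kernel (i*j/(i+j-2))^3 is undefined on a (1,1) edge"
            )
        return Fraction((i * j) ** 3, (i + j - 2) ** 3)
    raise KeyError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")


def index_kernel(part: EdgePartition, name: str, alpha=None) -> AffineCount | float:
    """Edge-sum route: sum of count * kernel(i, j) over the partition.

    Returns an exact :class:`AffineCount` when every kernel value is
    rational; a plain float for irrational Randic exponents on concrete
    partitions.
    """
    exact = AffineCount()
    inexact = 0.0
    saw_float = False
    for (i, j), count in part:
        k = kernel(name, i, j, alpha)
        if isinstance(k, Fraction):
            exact = exact + count * k
        else:
            saw_float = True
            if not count.is_constant:
                raise ValueError(
                    "irrational kernel on a parametric partition; "
                    "evaluate the partition at a concrete parameter first"
                )
            inexact += float(count.c0) * k
    if saw_float:
        if not exact.is_constant:
            raise ValueError("mixed exact/inexact terms on a parametric partition")
        return float(exact.c0) + inexact
    return exact


# ---------------------------------------------------------------------------
# Operator pipelines (literal Table-of-derivations forms)
# ---------------------------------------------------------------------------

def _pow(op, p, times: int):
    for _ in range(times):
        p = op(p)
    return p


def index_operator(p: MPoly, name: str, alpha=None) -> AffineCount:
    """Operator route: the literal pipeline evaluated at x = y = 1.

    Degenerate terms (AZI on a graph with a (1,1) edge) propagate as
    :class:`DegenerateTermError` from the integration step.
    """
    if name == "M1":
        return eval_at_one(op_dx(p) + op_dy(p))
    if name == "M2":
        return eval_at_one(op_dx(op_dy(p)))
    if name == "mM2":
        return eval_at_one(op_ix(op_iy(p)))
    if name == "Ralpha":
        a = DEFAULT_ALPHA if alpha is None else alpha
        if not _is_integral(a):
            raise UnsupportedOnThisRoute(
                f"alpha={a} is not an integer; use index_kernel for fractional exponents"
            )
        a = int(Fraction(a))
        if a >= 0:
            q = _pow(op_dx, p, a)
            q = _pow(op_dy, q, a)
        else:
            q = _pow(op_ix, p, -a)
            q = _pow(op_iy, q, -a)
        return eval_at_one(q)
    if name == "SDD":
        return eval_at_one(op_dx(op_iy(p)) + op_ix(op_dy(p)))
    if name == "H":
        return eval_at_one(op_ix_uni(op_j(p))) * 2
    if name == "I":
        return eval_at_one(op_ix_uni(op_j(op_dx(op_dy(p)))))
    if name == "F":
        q1 = op_dx(op_dx(p))
        q2 = op_dy(op_dy(p))
        return eval_at_one(q1 + q2)
    if name == "ReZG3":
        return eval_at_one(op_dx(op_dy(op_dx(p) + op_dy(p))))
    if name == "AZI":
        q = _pow(op_dy, p, 3)
        q = _pow(op_dx, q, 3)
        u = op_q(op_j(q), -2)
        u = _pow(op_ix_uni, u, 3)
        return eval_at_one(u)
    raise KeyError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")


# ---------------------------------------------------------------------------
# Batch convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexResult:
    """One index value with its provenance (which route produced it)."""

    name: str
    value: AffineCount | float | None
    route: str  # "operator" | "kernel"
    alpha: Fraction | None = None
    error: str | None = None

    def as_float(self) -> float:
        if self.value is None:
            raise ValueError(f"{self.name}: {self.error}")
        if isinstance(self.value, AffineCount):
            return float(self.value.constant_value())
        return float(self.value)


def all_indices(g: MolecularGraph, alphas=(DEFAULT_ALPHA,)) -> list[IndexResult]:
    """Compute every index on both routes for a concrete graph.

    AZI degeneracy (a (1,1) edge) is reported per-result via ``error``
    rather than aborting the whole batch.
    """
    part = edge_partition(g)
    poly = from_partition(part)
    results: list[IndexResult] = []
    for name in INDEX_NAMES:
        for alpha in (alphas if name == "Ralpha" else (None,)):
            a = Fraction(alpha) if alpha is not None else None
            try:
                kv = index_kernel(part, name, alpha=a)
            except (DegenerateEdgeError, ValueError) as exc:
                results.append(IndexResult(name, None, "kernel", a, str(exc)))
            else:
                results.append(IndexResult(name, kv, "kernel", a))
            if name == "Ralpha" and a is not None and not _is_integral(a):
                continue  # operator route deliberately absent for fractional alpha
            try:
                ov = index_operator(poly, name, alpha=a)
            except DegenerateTermError as exc:
                results.append(IndexResult(name, None, "operator", a, str(exc)))
            else:
                results.append(IndexResult(name, ov, "operator", a))
    return results


def format_value(value) -> str:
    """Presentation-layer rendering: 4 decimals, trailing zeros trimmed."""
    if value is None:
        return "NA"
    if isinstance(value, AffineCount):
        value = value.constant_value()
    text = f"{float(value):.4f}".rstrip("0").rstrip(".")
    return text if text not in ("", "-") else "0"


def indices_table(graphs, alphas=(DEFAULT_ALPHA,)) -> pd.DataFrame:
    """One row per graph, stable column order, kernel-route values.

    AZI degeneracy yields an NA cell, never an aborted batch.
    """
    columns = ["graph_id", "M1", "M2", "mM2", "H", "ReZG3", "SDD", "I", "F", "AZI"]
    columns += [f"R_alpha(alpha={Fraction(a)})" for a in alphas]
    rows = []
    for g in graphs:
        part = edge_partition(g)
        row: dict[str, object] = {"graph_id": g.name or f"graph{len(rows) + 1}"}
        for name in ("M1", "M2", "mM2", "H", "ReZG3", "SDD", "I", "F", "AZI"):
            try:
                row[name] = format_value(index_kernel(part, name))
            except DegenerateEdgeError:
                row[name] = "NA"
        for a in alphas:
            row[f"R_alpha(alpha={Fraction(a)})"] = format_value(
                index_kernel(part, "Ralpha", alpha=Fraction(a))
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
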