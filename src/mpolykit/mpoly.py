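"""The M-polynomial and its operator calculus.

For a graph G with m_ij edges whose endpoint degrees are (i, j), i <= j,

    M(G; x, y) = sum_{i<=j} m_ij x^i y^j.

Degree-based indices arise by applying combinations of six linear operators
and evaluating at x = y = 1:

    Dx p = x dp/dx            (coefficient of x^i y^j scales by i)
    Dy p = y dp/dy            (scales by j)
    Ix p = int_0^x p(t,y)/t dt  (divides by i; undefined when i = 0)
    Iy p = int_0^y p(x,t)/t dt  (divides by j)
    J p  = p(x, x)            (merges exponents, k = i + j)
    Q_a p = x^a p             (shifts the exponent by a)

All coefficients are :class:`AffineCount` (exact rationals, optionally
affine in one repeat parameter), so arbitrary operator chains stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .affine import AffineCount
from .graph_core import EdgePartition


class DegenerateTermError(ArithmeticError):
    """An integration operator hit a term with exponent zero.

    This is the failure mode of the augmented-Zagreb pipeline on a graph
    with a (1, 1) edge: J Dx^3 Dy^3 followed by Q_-2 produces a constant
    term whose Ix image would need division by zero.
    """


def _clean(terms: dict, cls, parameter_name):
    kept = {k: AffineCount.coerce(v) for k, v in terms.items()
            if not AffineCount.coerce(v).is_zero}
    return cls(kept, parameter_name)


@dataclass
class MPoly:
    """Sparse bivariate polynomial sum m_ij x^i y^j with affine coefficients."""

    terms: dict[tuple[int, int], AffineCount] = field(default_factory=dict)
    parameter_name: str | None = None

    def __post_init__(self) -> None:
        self.terms = {k: AffineCount.coerce(v) for k, v in self.terms.items()
                      if not AffineCount.coerce(v).is_zero}

    def __add__(self, other: "MPoly") -> "MPoly":
        out = dict(self.terms)
        for key, c in other.terms.items():
            out[key] = out.get(key, AffineCount()) + c
        return _clean(out, MPoly, self.parameter_name or other.parameter_name)

    def scale(self, scalar) -> "MPoly":
        return _clean({k: c * scalar for k, c in self.terms.items()},
                      MPoly, self.parameter_name)

    def render(self) -> str:
        """Human-readable rendering, lexicographic in (i, j)."""
        if not self.terms:
            return "0"
        parts = []
        for (i, j), c in sorted(self.terms.items()):
            coeff = c.render(self.parameter_name)
            if not c.is_constant:
                coeff = f"({coeff})"
            monomial = "*".join(s for s in
                                (f"x^{i}" if i != 1 else "x" if i else "",
                                 f"y^{j}" if j != 1 else "y" if j else "")
                                if s)
            parts.append(f"{coeff}*{monomial}" if monomial else coeff)
        return " + ".join(parts)

    def __str__(self) -> str:
        return self.render()


@dataclass
class UniPoly:
    """Univariate polynomial in x — the image of the J substitution y := x."""

    terms: dict[int, AffineCount] = field(default_factory=dict)
    parameter_name: str | None = None

    def __post_init__(self) -> None:
        self.terms = {k: AffineCount.coerce(v) for k, v in self.terms.items()
                      if not AffineCount.coerce(v).is_zero}

    def __add__(self, other: "UniPoly") -> "UniPoly":
        out = dict(self.terms)
        for key, c in other.terms.items():
            out[key] = out.get(key, AffineCount()) + c
        return _clean(out, UniPoly, self.parameter_name or other.parameter_name)

    def scale(self, scalar) -> "UniPoly":
        return _clean({k: c * scalar for k, c in self.terms.items()},
                      UniPoly, self.parameter_name)


# ---------------------------------------------------------------------------
# Construction and evaluation
# ---------------------------------------------------------------------------

def from_partition(part: EdgePartition) -> MPoly:
    """M-polynomial of an edge partition: term (i, j) carries |N(i,j)|."""
    return MPoly({key: count for key, count in part}, part.parameter_name)


def eval_at_one(p: MPoly | UniPoly) -> AffineCount:
    """Evaluate at x = y = 1: the exact sum of all coefficients.

    For the raw M-polynomial of a graph this is the edge count |E|.
    """
    out = AffineCount()
    for c in p.terms.values():
        out = out + c
    return out


# ---------------------------------------------------------------------------
# The six operators
# ---------------------------------------------------------------------------

def op_dx(p: MPoly) -> MPoly:
    return _clean({(i, j): c * i for (i, j), c in p.terms.items()},
                  MPoly, p.parameter_name)


def op_dy(p: MPoly) -> MPoly:
    return _clean({(i, j): c * j for (i, j), c in p.terms.items()},
                  MPoly, p.parameter_name)


def op_ix(p: MPoly) -> MPoly:
    out = {}
    for (i, j), c in p.terms.items():
        if i == 0:
            raise DegenerateTermError(
                f"Ix undefined on term with x-exponent 0 (coefficient {c})"
            )
        out[(i, j)] = c / i
    return _clean(out, MPoly, p.parameter_name)


def op_iy(p: MPoly) -> MPoly:
    out = {}
    for (i, j), c in p.terms.items():
        if j == 0:
            raise DegenerateTermError(
                f"Iy undefined on term with y-exponent 0 (coefficient {c})"
            )
        out[(i, j)] = c / j
    return _clean(out, MPoly, p.parameter_name)


def op_j(p: MPoly) -> UniPoly:
    """Substitute y := x; exponents merge as k = i + j, coefficients add."""
    out: dict[int, AffineCount] = {}
    for (i, j), c in p.terms.items():
        k = i + j
        out[k] = out.get(k, AffineCount()) + c
    return _clean(out, UniPoly, p.parameter_name)


def op_q(p: UniPoly, alpha: int) -> UniPoly:
    """Multiply by x^alpha: shift every exponent by alpha.

    Exponent 0 (or below) is tolerated here; a subsequent integration step
    is the place that rejects it.
    """
    return _clean({k + alpha: c for k, c in p.terms.items()},
                  UniPoly, p.parameter_name)


def op_dx_uni(p: UniPoly) -> UniPoly:
    return _clean({k: c * k for k, c in p.terms.items()}, UniPoly, p.parameter_name)


def op_ix_uni(p: UniPoly) -> UniPoly:
    out = {}
    for k, c in p.terms.items():
        if k == 0:
            raise DegenerateTermError(
                f"Ix undefined on constant term (coefficient {c})"
            )
        out[k] = c / k
    return _clean(out, UniPoly, p.parameter_name)
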