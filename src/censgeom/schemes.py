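"""Progressive Type-II censoring schemes and their combinatorial coefficients.

A progressive Type-II censored life test puts ``n`` items on test and observes
``m`` failures; at the r-th failure, ``R_r`` of the surviving items are removed,
so that ``sum(R) = n - m``.  Everything downstream — the joint likelihood
normalizer, the marginal densities of the individual censored order statistics,
and the information-geometric tensors — is driven by the *risk-set sizes*

    gamma_s = sum_{j >= s} (R_j + 1) = n - s + 1 - sum_{r < s} R_r,

the number of items still on test just before the s-th failure.  The scheme
arithmetic here is exact (Python integers / `fractions.Fraction`); only the
partial-fraction coefficients ``a_{s,r}`` are exposed in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SchemeError",
    "CensoringScheme",
    "validate_scheme",
    "named_scheme",
    "all_schemes",
    "parse_scheme",
    "format_scheme",
]


class SchemeError(ValueError):
    """A censoring scheme violating one of the admissibility constraints."""


@dataclass(frozen=True)
class CensoringScheme:
    """An admissible progressive Type-II censoring scheme ``(n, m, R)``.

    Instances are immutable; derived quantities (``gamma``, ``c(R)``, the
    marginal-density coefficients) are computed on demand and cached.
    """

    n: int
    m: int
    R: tuple[int, ...]

    def __post_init__(self) -> None:
        n, m, R = self.n, self.m, self.R
        if not (isinstance(n, int) and isinstance(m, int)):
            raise SchemeError(f"n and m must be integers, got n={n!r}, m={m!r}")
        if n < 1 or m < 1:
            raise SchemeError(f"n and m must be positive, got n={n}, m={m}")
        if m > n:
            raise SchemeError(f"m must not exceed n: m={m} > n={n}")
        R = tuple(int(r) for r in R)
        object.__setattr__(self, "R", R)
        if len(R) != m:
            raise SchemeError(f"R must have length m={m}, got length {len(R)}")
        if any(r < 0 for r in R):
            raise SchemeError(f"all removals R_r must be non-negative, got R={R}")
        if sum(R) != n - m:
            raise SchemeError(
                f"sum(R)={sum(R)} must equal n - m = {n - m} for R={R}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def gamma(self) -> tuple[int, ...]:
        """Risk-set sizes ``gamma_s = sum_{j>=s}(R_j + 1)``; strictly decreasing."""
        acc = 0
        out = []
        for r in reversed(self.R):
            acc += r + 1
            out.append(acc)
        return tuple(reversed(out))

    @property
    def normalizing_constant(self) -> int:
        """The joint-density normalizer ``c(R) = prod_s gamma_s`` (exact integer)."""
        return math.prod(self.gamma)

    def normalizing_constant_telescoping(self) -> int:
        """``c(R) = n (n - R_1 - 1)(n - R_1 - R_2 - 2) ...`` — the classical
        telescoping product; equals :attr:`normalizing_constant` identically."""
        out = 1
        removed = 0
        for s, r in enumerate(self.R, start=1):
            out *= self.n - removed - (s - 1)
            removed += r
        return out

    def marginal_coefficients(self, r: int) -> tuple[float, np.ndarray]:
        """Coefficients ``(c_{r-1}, a_{.,r})`` of the r-th marginal density.

        ``c_{r-1} = prod_{s<=r} gamma_s`` and
        ``a_{s,r} = prod_{k<=r, k!=s} 1/(gamma_k - gamma_s)`` with ``a_{1,1}=1``.
        """
        c_exact, a_exact = self.marginal_coefficients_exact(r)
        return float(c_exact), np.array([float(a) for a in a_exact])

    def marginal_coefficients_exact(self, r: int) -> tuple[int, list[Fraction]]:
        """Exact-rational version of :meth:`marginal_coefficients`."""
        if not 1 <= r <= self.m:
            raise SchemeError(f"r={r} out of range 1..{self.m}")
        g = self.gamma[:r]
        c = math.prod(g)
        a = []
        for s in range(r):
            denom = math.prod(g[k] - g[s] for k in range(r) if k != s)
            a.append(Fraction(1, denom))
        return c, a

    # -- serialization ------------------------------------------------------

    def scheme_string(self) -> str:
        return ",".join(str(r) for r in self.R)

    def __str__(self) -> str:
        return f"CensoringScheme(n={self.n}, m={self.m}, R=({self.scheme_string()}))"


def validate_scheme(n: int, m: int, R: Sequence[int]) -> CensoringScheme:
    """Validate ``(n, m, R)`` and return the immutable scheme.

    Raises :class:`SchemeError` naming the violated constraint otherwise.
    """
    return CensoringScheme(int(n), int(m), tuple(int(r) for r in R))


def named_scheme(n: int, m: int, kind: str) -> CensoringScheme:
    """Construct one of the three standard scheme families.

    * ``R1`` — conventional Type-II: all removals at the last failure.
    * ``R2`` — all removals at the first failure.
    * ``R3`` — one removal at each of the first m-1 failures, the rest at the
      last (requires ``n >= 2m - 1``).
    """
    if m > n:
        raise SchemeError(f"m must not exceed n: m={m} > n={n}")
    kind = kind.upper()
    if kind == "R1":
        R = (0,) * (m - 1) + (n - m,)
    elif kind == "R2":
        R = (n - m,) + (0,) * (m - 1)
    elif kind == "R3":
        if n - 2 * m + 1 < 0:
            raise SchemeError(
                f"scheme R3 infeasible: n - 2m + 1 = {n - 2 * m + 1} < 0"
            )
        R = (1,) * (m - 1) + (n - 2 * m + 1,)
    else:
        raise SchemeError(f"unknown named scheme kind {kind!r}; use R1, R2 or R3")
    return CensoringScheme(n, m, R)


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def all_schemes(n: int) -> Iterator[CensoringScheme]:
    """Enumerate every admissible scheme with ``n`` items (all m, all R)."""
    for m in range(1, n + 1):
        for R in _compositions(n - m, m):
            yield CensoringScheme(n, m, R)


def parse_scheme(n: int, m: int, text: str) -> CensoringScheme:
    """Parse a comma-separated removal string such as ``"0,0,3,0,3,0,0,5"``."""
    R = tuple(int(tok) for tok in text.split(","))
    return validate_scheme(n, m, R)


def format_scheme(scheme: CensoringScheme) -> str:
    return scheme.scheme_string()
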