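"""Fractional-polynomial bases for trajectory shapes.

A fractional polynomial (FP) of degree m uses powers drawn (with repetition)
from a fixed set, conventionally {-2, -1, -0.5, 0, 0.5, 1, 2, 3}.  Power 0
denotes log(x), and a repeated power p contributes the pair x^p and
x^p * log(x).  Ages are affinely rescaled before exponentiation so that the
transformed time variable is strictly positive and well conditioned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: The conventional candidate power set for fractional polynomials.
FP_POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class BasisDomainError(ValueError):
    """Transformed ages are outside the domain of the requested powers."""


@dataclass(frozen=True)
class FPBasis:
    """A fractional-polynomial basis of degree <= 2 on rescaled age.

    Parameters
    ----------
    powers
        Ordered multiset of powers.  Power 0 means log(x); a repeated
        power p expands to the columns x^p and x^p*log(x).
    offset, divisor
        Age is transformed as t = (age - offset) / divisor before the
        powers are applied.  The default (0, 10) maps the cohort's age
        range 10-25 years onto t in [1, 2.5].
    """

    powers: tuple[float, ...] = (1.0, 2.0)
    offset: float = 0.0
    divisor: float = 10.0

    def __post_init__(self) -> None:
        if len(self.powers) == 0:
            raise ValueError("FPBasis requires at least one power")
        pws = tuple(float(p) for p in self.powers)
        if tuple(sorted(pws)) != pws:
            pws = tuple(sorted(pws))
        object.__setattr__(self, "powers", pws)
        if self.divisor == 0:
            raise ValueError("divisor must be nonzero")

    @property
    def degree(self) -> int:
        return len(self.powers)

    @property
    def n_columns(self) -> int:
        """Number of design columns including the intercept."""
        return 1 + len(self.powers)

    def transform_age(self, ages: np.ndarray) -> np.ndarray:
        return (np.asarray(ages, dtype=float) - self.offset) / self.divisor

    def label(self) -> str:
        return "FP(" + ",".join(f"{p:g}" for p in self.powers) + ")"


def build_fp_basis(ages: np.ndarray, basis: FPBasis) -> np.ndarray:
    """Evaluate the FP design matrix at ``ages``.

    Columns are ordered (intercept, powers ascending); a repeated power p
    contributes t^p followed by t^p*log(t).

    Raises
    ------
    BasisDomainError
        If any transformed age is nonpositive (log and fractional/negative
        powers are then undefined).
    """
    t = basis.transform_age(ages)
    if np.any(~np.isfinite(t)):
        raise BasisDomainError("non-finite age after transform")
    if np.any(t <= 0):
        raise BasisDomainError(
            f"transformed ages must be strictly positive, got min {t.min():g}"
        )
    cols = [np.ones_like(t)]
    logt = np.log(t)
    prev: float | None = None
    for p in basis.powers:
        base = logt if p == 0 else t**p
        if prev is not None and p == prev:
            # repeated power: second column picks up the log factor
            base = (logt if p == 0 else t**p) * logt
        cols.append(base)
        prev = p
    return np.column_stack(cols)


def enumerate_fp_specs(
    power_set: tuple[float, ...] = FP_POWER_SET,
    max_degree: int = 2,
    offset: float = 0.0,
    divisor: float = 10.0,
) -> list[FPBasis]:
    """All FP bases up to ``max_degree`` over ``power_set``.

    Degree-2 bases are multisets with repetition, so the default 8-power
    set yields 8 + (C(8,2) + 8) = 44 specifications.
    """
    if len(power_set) == 0:
        raise ValueError("power_set must be nonempty")
    specs: list[FPBasis] = []
    for degree in range(1, max_degree + 1):
        for combo in itertools.combinations_with_replacement(sorted(power_set), degree):
            specs.append(FPBasis(powers=combo, offset=offset, divisor=divisor))
    return specs
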