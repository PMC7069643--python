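"""Compositional algebra on the simplex (Aitchison geometry).

A leaf ionome is a composition: a vector of strictly positive parts that
carries only relative information and is closed to a constant sum. The
canonical representation here is the 6-part foliar composition
``(N, P, K, Mg, Ca, Fv)``, where ``Fv`` is the *filling value* — the
unquantified remainder of the tissue dry matter, amalgamated into a single
component so that the five measured nutrients live in a complete simplex.

The module implements the primitives the diagnosis rests on:

* ``close`` — projection of a positive vector onto the unit simplex;
* ``clr_transform`` / ``clr_inverse`` — the centred log-ratio isometry
  between the simplex and the sum-zero hyperplane of R^D;
* ``perturb`` / ``perturbation_difference`` — the simplex group operation
  (component-wise product followed by closure) and its inverse, the
  compositional analogue of translation and subtraction;
* ``aitchison_distance`` — Euclidean distance between clr images, the
  natural metric of the simplex;
* ``rank_imbalance`` — ordering of nutrients by apparent excess or
  deficiency from a clr difference.

No zero replacement is performed here: inputs must be strictly positive,
which upstream filtering guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NUTRIENTS",
    "PARTS",
    "Composition",
    "ClrVector",
    "ImbalanceEntry",
    "close",
    "clr_transform",
    "clr_inverse",
    "perturb",
    "perturbation_difference",
    "subcomposition",
    "aitchison_distance",
    "rank_imbalance",
]

#: Measured foliar nutrients, in the canonical order used throughout.
NUTRIENTS: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca")

#: Full 6-part composition: the five nutrients plus the filling value.
PARTS: tuple[str, ...] = NUTRIENTS + ("Fv",)

_CLOSE_TOL = 1e-9


class CompositionError(ValueError):
    """Raised for vectors that cannot represent a valid composition."""


class PartAlignmentError(KeyError):
    """Raised when part labels of two compositions do not match."""


def _as_float_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1:
        raise CompositionError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Composition:
    """A D-part composition: positive values closed to unit sum.

    Parameters
    ----------
    values : array-like of float
        Strictly positive parts; they are validated, not re-closed — use
        :func:`close` to build a composition from raw positive data.
    parts : tuple of str
        Unique component labels, same length as ``values``.
    """

    values: np.ndarray
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "parts", tuple(self.parts))
        if len(self.parts) != arr.size:
            raise CompositionError(
                f"{len(self.parts)} part labels for {arr.size} values")
        if len(set(self.parts)) != len(self.parts):
            raise CompositionError("part labels must be unique")
        if not np.all(np.isfinite(arr)):
            raise CompositionError("non-finite component")
        if np.any(arr <= 0):
            raise CompositionError("every component must be strictly positive")
        if abs(arr.sum() - 1.0) > _CLOSE_TOL:
            raise CompositionError(
                f"components sum to {arr.sum():.12g}, not 1; apply close() first")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, part: str) -> float:
        try:
            return float(self.values[self.parts.index(part)])
        except ValueError:
            raise PartAlignmentError(part) from None

    def asdict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(self.parts, self.values)}


# A perturbation vector is itself a composition acting multiplicatively.
PerturbationVector = Composition


@dataclass(frozen=True)
class ClrVector:
    """Centred log-ratio image of a composition: a sum-zero real vector."""

    values: np.ndarray
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "parts", tuple(self.parts))
        if len(self.parts) != arr.size:
            raise CompositionError(
                f"{len(self.parts)} part labels for {arr.size} values")
        if not np.all(np.isfinite(arr)):
            raise CompositionError("non-finite clr value")
        if abs(arr.sum()) > 1e-8:
            raise CompositionError(
                f"clr values sum to {arr.sum():.3g}, expected 0")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, part: str) -> float:
        try:
            return float(self.values[self.parts.index(part)])
        except ValueError:
            raise PartAlignmentError(part) from None


def close(raw: Iterable[float], parts: Sequence[str] = PARTS) -> Composition:
    """Close a strictly positive vector to unit sum.

    The closure operator C rescales a positive vector onto the simplex,
    preserving all component ratios. Idempotent on compositions.
    """
    arr = _as_float_array(raw)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise CompositionError("closure requires strictly positive finite entries")
    return Composition(arr / arr.sum(), tuple(parts))


def clr_transform(c: Composition) -> ClrVector:
    """Centred log-ratio transform: clr_i = ln(x_i / g(x)).

    ``g(x)`` is the geometric mean over *all* components, including the
    filling value when present. The image always sums to zero.
    """
    logs = np.log(c.values)
    centred = logs - logs.mean()
    return ClrVector(centred - centred.mean(), c.parts)


def clr_inverse(v: ClrVector) -> Composition:
    """Back-transform a clr vector to the simplex via exp and closure.

    Closure absorbs any additive constant, so un-centred log vectors map to
    the same composition as their centred versions.
    """
    if np.any(np.abs(v.values) > 500):
        raise CompositionError("clr values too extreme to exponentiate")
    return close(np.exp(v.values), v.parts)


def _check_aligned(a: Composition, b: Composition) -> None:
    if a.parts != b.parts:
        raise PartAlignmentError(
            f"part labels differ: {a.parts} vs {b.parts}")


def perturb(a: Composition, p: PerturbationVector) -> Composition:
    """Perturbation a ⊕ p = C(a_1 p_1, …, a_D p_D): translation on the simplex."""
    _check_aligned(a, p)
    return close(a.values * p.values, a.parts)


def perturbation_difference(a: Composition, b: Composition) -> PerturbationVector:
    """The perturbation vector b ⊖ a = C(b/a) taking ``a`` onto ``b``.

    Equivalently the clr difference clr(b) − clr(a) back-transformed to the
    simplex; satisfies ``perturb(a, perturbation_difference(a, b)) == b``.
    """
    _check_aligned(a, b)
    return close(b.values / a.values, a.parts)


def subcomposition(c: Composition, keep: Sequence[str]) -> Composition:
    """Re-close a composition over a subset of parts, order preserved.

    The kept parts retain their original relative order in ``c.parts``;
    at least two parts are required for the result to be a composition.
    """
    keep_set = set(keep)
    unknown = keep_set - set(c.parts)
    if unknown:
        raise PartAlignmentError(f"unknown parts: {sorted(unknown)}")
    if len(keep_set) < 2:
        raise CompositionError("a subcomposition needs at least 2 parts")
    idx = [i for i, p in enumerate(c.parts) if p in keep_set]
    return close(c.values[idx], tuple(c.parts[i] for i in idx))


def aitchison_distance(
    a: Composition,
    b: Composition,
    parts: Sequence[str] | None = NUTRIENTS,
) -> float:
    """Aitchison distance between two compositions.

    Euclidean norm of the difference of clr images, computed on the
    subcomposition over ``parts``. The default restricts to the five
    measured nutrients, excluding the filling value: the diagnosis
    quantifies imbalance among the nutrients themselves, and the filling
    value is an amalgam of everything unmeasured. Pass ``parts=None`` or
    the full label tuple for the all-parts distance.

    Invariant under perturbation: d(a ⊕ c, b ⊕ c) = d(a, b).
    """
    if parts is None:
        parts = a.parts
    sa = subcomposition(a, parts) if tuple(parts) != a.parts else a
    sb = subcomposition(b, parts) if tuple(parts) != b.parts else b
    _check_aligned(sa, sb)
    diff = clr_transform(sa).values - clr_transform(sb).values
    return float(np.linalg.norm(diff))


@dataclass(frozen=True)
class ImbalanceEntry:
    """One nutrient's apparent status relative to a balanced reference."""

    part: str
    status: str  # "deficient" | "excess"
    magnitude: float  # |clr(reference) - clr(observed)|


def rank_imbalance(
    delta: ClrVector,
    parts: Sequence[str] = NUTRIENTS,
    atol: float = 1e-12,
) -> list[ImbalanceEntry]:
    """Rank nutrients by apparent excess or deficiency.

    ``delta`` is the clr difference *reference − observed*. A positive
    delta means the balanced reference carries relatively more of the
    nutrient than the observed specimen — the nutrient is apparently
    deficient; a negative delta marks an apparent excess. Entries are
    sorted by decreasing magnitude; parts with |delta| <= atol are
    considered balanced and omitted.
    """
    entries = []
    for p in parts:
        d = delta[p]
        if abs(d) <= atol:
            continue
        entries.append(ImbalanceEntry(
            part=p,
            status="deficient" if d > 0 else "excess",
            magnitude=abs(d),
        ))
    entries.sort(key=lambda e: -e.magnitude)
    return entries
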