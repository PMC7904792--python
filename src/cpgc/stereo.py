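"""Stereogenic centers and diastereomer counting for CP congeners.

A carbon of a polychlorinated n-alkane is stereogenic when it carries
exactly one chlorine, is internal (terminal CH2Cl has two identical H;
CCl3 has three identical Cl), and its two chain-side substituents are
constitutionally distinct. CCl2 carbons are never stereogenic.

Stereoisomers are modelled abstractly: one binary configuration label per
center (standing in for R/S), ordered by carbon position. Two symmetry
operations act on configuration vectors:

* ``mirror`` — reflection of the whole molecule, negating every label.
  Enantiomer pairs are identified, because partition coefficients of
  enantiomers are equal in isotropic phases; "diastereomer" here therefore
  means an orbit under the mirror.
* ``flip`` — the end-to-end rotation of the chain, available only when the
  chlorination pattern is flip-symmetric. A proper rotation preserves
  configuration labels and only permutes the centers (``p -> n+1-p``).

Counting is done by brute-force orbit enumeration over all ``2^k``
configuration vectors and cross-checked against the closed-form Burnside
(orbit-counting) lemma; the two must agree for every congener.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .congener import Congener, flip_symmetry
from .exceptions import TooManyCentersError

__all__ = [
    "StereoAssignment",
    "stereo_centers",
    "count_diastereomers",
    "count_diastereomers_burnside",
    "count_stereoisomers",
    "enumerate_diastereomers",
    "DEFAULT_CENTER_CAP",
]

#: default bound on the number of stereocenters for the 2^k enumeration
DEFAULT_CENTER_CAP = 20


def stereo_centers(c: Congener) -> list[int]:
    """Carbon positions of the stereogenic centers, ascending.

    A position qualifies iff it is internal, carries exactly one Cl, and
    the two outward-read side sequences of (carbon, Cl-count) differ. The
    side comparison also excludes pseudo-asymmetric middle carbons of
    flip-symmetric odd chains, keeping the group action label-consistent.
    """
    n = c.chain_length
    counts = c.as_dict()
    centers = []
    for p in range(2, n):
        if counts.get(p, 0) != 1:
            continue
        left = tuple(counts.get(q, 0) for q in range(p - 1, 0, -1))
        right = tuple(counts.get(q, 0) for q in range(p + 1, n + 1))
        if left != right:
            centers.append(p)
    return centers


def _flip_index_map(centers: Sequence[int], chain_length: int) -> list[int]:
    """Index permutation of centers induced by the chain flip.

    Only meaningful when the congener is flip-symmetric, in which case the
    flip maps the center set onto itself.
    """
    pos_to_idx = {p: i for i, p in enumerate(centers)}
    return [pos_to_idx[chain_length + 1 - p] for p in centers]


def _group_elements(
    k: int, flip_map: Sequence[int] | None, include_mirror: bool = True
) -> list[tuple[Sequence[int] | None, bool]]:
    """Group elements as (index permutation or None for identity, negate?)."""
    elems: list[tuple[Sequence[int] | None, bool]] = [(None, False)]
    if include_mirror:
        elems.append((None, True))
    if flip_map is not None:
        elems.append((flip_map, False))
        if include_mirror:
            elems.append((flip_map, True))
    return elems


def _apply(vec: tuple[int, ...], perm: Sequence[int] | None, negate: bool) -> tuple[int, ...]:
    out = vec if perm is None else tuple(vec[j] for j in perm)
    return tuple(1 - b for b in out) if negate else out


def _orbit_min(vec, elems) -> tuple[int, ...]:
    return min(_apply(vec, perm, neg) for perm, neg in elems)


def _centers_and_flip(c: Congener, cap: int):
    centers = stereo_centers(c)
    if len(centers) > cap:
        raise TooManyCentersError(
            f"{c.name} has {len(centers)} stereocenters, above the cap of {cap}; "
            "raise the cap to enumerate 2^k configurations anyway"
        )
    flip_map = _flip_index_map(centers, c.chain_length) if flip_symmetry(c) else None
    return centers, flip_map


def _enumerated_count(k: int, flip_map, include_mirror: bool = True) -> int:
    elems = _group_elements(k, flip_map, include_mirror)
    n_orbits = 0
    for vec in product((0, 1), repeat=k):
        if vec == _orbit_min(vec, elems):
            n_orbits += 1
    return n_orbits


def _burnside_count(k: int, flip_map, include_mirror: bool = True) -> int:
    """Closed-form orbit count via the Burnside (Cauchy-Frobenius) lemma.

    Fixed-point counts: identity fixes all 2^k vectors; the mirror fixes
    none for k >= 1 (a vector cannot equal its own negation); the flip
    fixes 2^(number of cycles); flip-with-mirror fixes 2^(number of
    2-cycles) when the center permutation is fixed-point free, else 0.
    """
    total = 2**k
    order = 1
    if include_mirror:
        order += 1
        total += 1 if k == 0 else 0
    if flip_map is not None:
        order += 1
        # cycle structure of the involution: f fixed points, t transpositions
        fixed = sum(1 for i, j in enumerate(flip_map) if i == j)
        two_cycles = (k - fixed) // 2
        total += 2 ** (fixed + two_cycles)
        if include_mirror:
            order += 1
            total += 0 if fixed else 2**two_cycles
    count, rem = divmod(total, order)
    if rem:  # group theory guarantees divisibility; guard arithmetic slips
        raise AssertionError("Burnside sum not divisible by group order")
    return count


def count_diastereomers(c: Congener, cap: int = DEFAULT_CENTER_CAP) -> int:
    """Number of diastereomers of ``c``, enantiomer pairs counted once.

    Orbits of ``{0,1}^k`` under {identity, mirror}, extended by the chain
    flip when the chlorination pattern is flip-symmetric. Counted by
    exhaustive orbit enumeration and verified against the Burnside
    closed form; a congener without stereocenters counts as 1 structure.
    """
    centers, flip_map = _centers_and_flip(c, cap)
    k = len(centers)
    enumerated = _enumerated_count(k, flip_map)
    analytic = _burnside_count(k, flip_map)
    if enumerated != analytic:  # pragma: no cover - internal consistency
        raise AssertionError(
            f"orbit enumeration ({enumerated}) disagrees with Burnside ({analytic}) "
            f"for {c.name}"
        )
    return enumerated


def count_diastereomers_burnside(c: Congener, cap: int = DEFAULT_CENTER_CAP) -> int:
    """Analytic diastereomer count (Burnside only, no enumeration).

    Independent closed form used to cross-check :func:`count_diastereomers`.
    """
    centers, flip_map = _centers_and_flip(c, cap)
    return _burnside_count(len(centers), flip_map)


def count_stereoisomers(
    c: Congener, cap: int = DEFAULT_CENTER_CAP, include_flip: bool | None = None
) -> int:
    """Number of distinct stereoisomer structures, mirror images counted apart.

    Orbits under {identity, flip} (flip only when applicable, or forced via
    ``include_flip``). Always >= :func:`count_diastereomers`, with equality
    iff every stereoisomer is achiral (meso).
    """
    centers, flip_map = _centers_and_flip(c, cap)
    if include_flip is False:
        flip_map = None
    return _enumerated_count(len(centers), flip_map, include_mirror=False)


@dataclass(frozen=True, eq=False)
class StereoAssignment:
    """One stereoisomer of a congener, up to the abstract configuration model.

    ``config`` holds one binary label per stereogenic center, centers in
    ascending carbon position. Equality and hashing identify assignments in
    the same symmetry orbit (so an assignment equals its mirror image).
    """

    congener: Congener
    config: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(stereo_centers(self.congener))
        if len(self.config) != k:
            raise ValueError(
                f"config length {len(self.config)} != {k} stereocenters of "
                f"{self.congener.name}"
            )
        if any(b not in (0, 1) for b in self.config):
            raise ValueError("config labels must be 0 or 1")

    def canonical_config(self) -> tuple[int, ...]:
        """Lexicographically smallest configuration in this orbit."""
        centers, flip_map = _centers_and_flip(self.congener, len(self.config))
        return _orbit_min(self.config, _group_elements(len(centers), flip_map))

    @property
    def stereoisomer_id(self) -> str:
        """Stable label, e.g. ``"d0110"`` (empty config -> ``"d-"``)."""
        return "d" + ("".join(str(b) for b in self.config) or "-")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StereoAssignment):
            return NotImplemented
        return (
            self.congener == other.congener
            and self.canonical_config() == other.canonical_config()
        )

    def __hash__(self) -> int:
        return hash((self.congener, self.canonical_config()))


def enumerate_diastereomers(
    c: Congener, cap: int = DEFAULT_CENTER_CAP
) -> list[StereoAssignment]:
    """One canonical representative per diastereomer orbit, in lexicographic order.

    The representative of an orbit is its lexicographically smallest
    configuration vector; the list length equals
    :func:`count_diastereomers`.
    """
    centers, flip_map = _centers_and_flip(c, cap)
    elems = _group_elements(len(centers), flip_map)
    reps = [
        StereoAssignment(c, vec)
        for vec in product((0, 1), repeat=len(centers))
        if vec == _orbit_min(vec, elems)
    ]
    return reps
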