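"""Constitutional model of chlorinated-paraffin (CP) congeners.

A CP congener is a linear *n*-alkane skeleton with chlorine substituents.
The field's positional notation writes one locant per chlorine atom, e.g.
``"1,1,1,3-C10Cl4"`` for a decane with a CCl3 group at C1 and one Cl at C3.
Carbon positions are 1-based throughout, as in chemical nomenclature.

The two numbering directions of a chain describe the same molecule, so a
canonical direction is chosen: of the identity and the end-to-end flip
(``p -> n+1-p``), the one whose sorted locant list is lexicographically
smaller is stored (lowest-locant rule); flip-symmetric patterns keep the
identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .exceptions import (
    ChlorineCountMismatchError,
    MalformedNameError,
    MultiplicityError,
    PositionRangeError,
)

__all__ = [
    "Congener",
    "parse_congener",
    "flip_symmetry",
    "read_congener_list",
]

_NAME_RE = re.compile(r"^(?P<locants>\d+(?:,\d+)*)-C(?P<n>\d+)Cl(?P<m>\d+)$")

#: valence caps: at most 3 Cl on a terminal carbon, 2 on an internal one
_MAX_CL_TERMINAL = 3
_MAX_CL_INTERNAL = 2


def _flip_counts(chain_length: int, counts: Mapping[int, int]) -> dict[int, int]:
    return {chain_length + 1 - p: c for p, c in counts.items()}


def _locant_list(counts: Mapping[int, int]) -> tuple[int, ...]:
    """Sorted locants, each repeated per Cl multiplicity."""
    out: list[int] = []
    for p in sorted(counts):
        out.extend([p] * counts[p])
    return tuple(out)


@dataclass(frozen=True)
class Congener:
    """A validated, canonically numbered CP congener.

    Parameters
    ----------
    chain_length : int
        Number of skeleton carbons, ``>= 2``.
    cl_counts : tuple of (position, multiplicity) pairs
        Chlorine multiplicity per substituted carbon. Any mapping or pair
        iterable is accepted; it is normalised, validated and canonicalised
        on construction. Hydrogen counts are implicit.
    """

    chain_length: int
    cl_counts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        n = self.chain_length
        if not isinstance(n, int) or n < 2:
            raise MalformedNameError(f"chain length must be an integer >= 2, got {n!r}")
        raw = dict(self.cl_counts)
        counts: dict[int, int] = {}
        for p, c in raw.items():
            if not (1 <= p <= n):
                raise PositionRangeError(
                    f"position {p} outside chain 1..{n}"
                )
            if c < 0:
                raise MultiplicityError(f"negative Cl count {c} at position {p}")
            if c == 0:
                continue
            cap = _MAX_CL_TERMINAL if p in (1, n) else _MAX_CL_INTERNAL
            if c > cap:
                raise MultiplicityError(
                    f"{c} Cl at position {p} exceeds the cap of {cap} for a "
                    f"{'terminal' if p in (1, n) else 'internal'} carbon"
                )
            counts[p] = c
        if sum(counts.values()) < 1:
            raise MalformedNameError("a congener carries at least one chlorine")
        # canonical direction: lexicographically smallest sorted locant list
        flipped = _flip_counts(n, counts)
        if _locant_list(flipped) < _locant_list(counts):
            counts = flipped
        object.__setattr__(
            self, "cl_counts", tuple(sorted(counts.items()))
        )

    # -- accessors ---------------------------------------------------------

    def as_dict(self) -> dict[int, int]:
        """Cl multiplicity per substituted carbon position."""
        return dict(self.cl_counts)

    def cl_count(self, position: int) -> int:
        """Cl multiplicity at ``position`` (0 if unsubstituted)."""
        return dict(self.cl_counts).get(position, 0)

    @property
    def n_chlorines(self) -> int:
        return sum(c for _, c in self.cl_counts)

    @property
    def name(self) -> str:
        """Canonical positional-notation rendering, e.g. ``"1,1,1,3-C10Cl4"``."""
        locants = _locant_list(dict(self.cl_counts))
        return (
            ",".join(str(p) for p in locants)
            + f"-C{self.chain_length}Cl{self.n_chlorines}"
        )

    def flipped(self) -> "Congener":
        """The same molecule numbered from the other chain end.

        Canonicalisation makes this a no-op on the stored form; exposed for
        symmetry checks and property tests.
        """
        return Congener(
            self.chain_length,
            tuple(_flip_counts(self.chain_length, dict(self.cl_counts)).items()),
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_congener(name: str) -> Congener:
    """Parse positional notation like ``"2,5,6,9-C10Cl4"`` into a :class:`Congener`.

    The locant list carries one entry per chlorine atom (repeated locants
    denote multiple Cl on one carbon) and must agree with the ``Cl<m>``
    suffix. The result is canonicalised, so parsing then rendering then
    parsing is idempotent.

    Raises
    ------
    MalformedNameError, PositionRangeError, MultiplicityError,
    ChlorineCountMismatchError
        Each names the offending token.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise MalformedNameError(
            f"{name!r} does not match '<p1,p2,...>-C<n>Cl<m>' positional notation"
        )
    locants = [int(tok) for tok in m.group("locants").split(",")]
    n = int(m.group("n"))
    n_cl = int(m.group("m"))
    if n < 2:
        raise MalformedNameError(f"chain length {n} in {name!r} must be >= 2")
    if n_cl != len(locants):
        raise ChlorineCountMismatchError(
            f"{name!r} declares Cl{n_cl} but lists {len(locants)} locants"
        )
    for p in locants:
        if not (1 <= p <= n):
            raise PositionRangeError(f"position {p} in {name!r} outside chain 1..{n}")
    counts: dict[int, int] = {}
    for p in locants:
        counts[p] = counts.get(p, 0) + 1
    return Congener(n, tuple(counts.items()))


def flip_symmetry(c: Congener) -> bool:
    """True iff the chlorination pattern is invariant under the chain flip.

    Flip-symmetric congeners (e.g. 2,3,4,5,6,7,8,9-C10Cl8) admit the
    end-to-end rotation as an extra symmetry in stereoisomer counting.
    """
    counts = c.as_dict()
    return counts == _flip_counts(c.chain_length, counts)


def read_congener_list(path: str | Path) -> list[Congener]:
    """Read a plain-text congener list: one name per line, ``#`` comments allowed."""
    out: list[Congener] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(parse_congener(line))
    return out
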