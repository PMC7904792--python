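"""Exception hierarchy for cpgc.

All validation failures raise subclasses of :class:`ValueError` so callers
can catch broadly, while the distinct types let tests and the CLI name the
offending input precisely.
"""


class CongenerError(ValueError):
    """Base class for invalid congener definitions or names."""


class MalformedNameError(CongenerError):
    """Positional-notation string does not match ``p1,p2,...-C<n>Cl<m>``."""


class PositionRangeError(CongenerError):
    """A chlorine locant lies outside ``1..chain_length``."""


class MultiplicityError(CongenerError):
    """Chlorine multiplicity exceeds the valence cap (3 terminal, 2 internal)."""


class ChlorineCountMismatchError(CongenerError):
    """The ``Cl<m>`` suffix disagrees with the number of listed locants."""


class TooManyCentersError(ValueError):
    """Stereocenter count exceeds the enumeration cap."""


class LadderError(ValueError):
    """Invalid n-alkane ladder (too short, or not strictly increasing)."""


class OutOfRangeError(ValueError):
    """Retention time or elution temperature outside the reference span."""


class SingularDesignError(ValueError):
    """Regression design matrix is rank deficient."""


class UnidentifiableError(ValueError):
    """Too few, or collinear, polar columns: S and A cannot be separated."""


class NoCrossingError(ValueError):
    """log K(T) never crosses the characteristic value (zero van't Hoff slope)."""


class CalibrationError(ValueError):
    """Characteristic log K* calibration failed (no bracket / degenerate input)."""
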