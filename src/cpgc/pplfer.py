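"""ppLFER calibration and CP solute-descriptor derivation.

The Abraham poly-parameter linear free energy relationship for gas to
condensed-phase partitioning is

    log K = c + eE + sS + aA + bB + lL,

with solute descriptors E (excess molar refraction), S (dipolarity/
polarizability), A (H-bond donation), B (H-bond acceptance), L (log
hexadecane-air partition coefficient) and lowercase system parameters of
the phase. Here the temperature-programmed RI stands in for log K — an
approximation adequate for comparing congeners semi-quantitatively. None
of the GC phases donates H-bonds, so b = 0 throughout, and CP B values are
never estimated.

The three-stage derivation for CP congeners:

1. calibrate the nonpolar reference column with RI = c + eE + lL
   (s = a = 0 by construction) on reference compounds;
2. invert it per CP: L = (RI - c - eE) / l;
3. calibrate each polar column with RI = c + eE + sS + aA + lL, then solve
   per CP the zero-intercept system RI_j - c_j - e_j E - l_j L = s_j S + a_j A
   across polar columns j, optionally omitting columns to probe robustness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import SingularDesignError, UnidentifiableError

__all__ = [
    "SoluteDescriptors",
    "PPLFERSystem",
    "SAResult",
    "calibrate_nonpolar",
    "calibrate_polar",
    "derive_L",
    "derive_SA",
    "calibrate_columns",
    "derive_cp_descriptors",
]


@dataclass(frozen=True)
class SoluteDescriptors:
    """Abraham descriptors of one solute; ``B`` is NaN for CPs (not derived)."""

    compound_id: str
    E: float = 0.0
    S: float = 0.0
    A: float = 0.0
    B: float = float("nan")
    L: float = 0.0
    stderr: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.L):
            raise ValueError(f"L must be finite, got {self.L!r} for {self.compound_id}")


@dataclass(frozen=True)
class PPLFERSystem:
    """Calibrated system parameters of one GC column, RI response.

    ``e`` (or other coefficients) may be NaN when the calibration set gave
    the descriptor no variance — "not estimable"; prediction then treats
    the term as zero. ``b`` is 0 for every column here.
    """

    column_id: str
    c: float
    e: float
    s: float
    a: float
    l: float
    b: float = 0.0
    stderr: Mapping[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    sd: float = float("nan")
    n: int = 0

    @property
    def is_nonpolar(self) -> bool:
        return self.s == 0.0 and self.a == 0.0

    def predict_ri(self, E=0.0, S=0.0, A=0.0, L=0.0) -> float:
        """RI from the calibrated equation; non-estimable terms contribute 0."""
        terms = (self.c, self.e * E, self.s * S, self.a * A, self.l * L)
        return float(sum(0.0 if math.isnan(t) else t for t in terms))


def _ols(
    y: np.ndarray, cols: dict[str, np.ndarray], *, intercept: bool, min_n: int
) -> tuple[dict[str, float], dict[str, float], float, float, int]:
    """OLS with constant-column pruning.

    Descriptor columns without variance (all-equal values) are dropped and
    reported as NaN ("not estimable"); a rank-deficient design among the
    remaining columns raises :class:`SingularDesignError` naming them.
    Returns (coefficients, standard errors, R^2, residual SD, n).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_n:
        raise ValueError(f"need at least {min_n} reference compounds, got {n}")
    kept: list[str] = []
    dropped: list[str] = []
    for name, v in cols.items():
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0.0:
            if v[0] != 0.0:
                # constant nonzero descriptor: collinear with the intercept
                raise SingularDesignError(
                    f"descriptor {name!r} is constant ({v[0]:g}) across the "
                    "calibration set; the design is singular"
                )
            # identically zero: the term vanishes, coefficient not estimable
            dropped.append(name)
        else:
            kept.append(name)
    X = np.column_stack([np.asarray(cols[name], dtype=float) for name in kept]) if kept else np.empty((n, 0))
    names = list(kept)
    if intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["c"] + names
    if X.shape[1] == 0:
        raise SingularDesignError("empty design: no varying descriptors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"collinear design among {names}; descriptors are not separable"
        )
    res = sm.OLS(y, X).fit()
    coefs = dict(zip(names, res.params))
    ses = dict(zip(names, res.bse))
    for name in dropped:
        coefs[name] = float("nan")
        ses[name] = float("nan")
    dof = n - X.shape[1]
    sd = float(np.sqrt(res.ssr / dof)) if dof > 0 else float("nan")
    return coefs, ses, float(res.rsquared), sd, n


def calibrate_nonpolar(
    refs: pd.DataFrame, column_id: str = ""
) -> PPLFERSystem:
    """Calibrate a nonpolar column: RI = c + eE + lL on reference compounds.

    ``refs`` needs columns ``ri, E, L``; at least 4 compounds spanning a
    range of E and L. The polar parameters s and a are fixed at 0 by
    construction (the phase exerts only van der Waals retention).
    """
    coefs, ses, r2, sd, n = _ols(
        refs["ri"].to_numpy(),
        {"e": refs["E"].to_numpy(), "l": refs["L"].to_numpy()},
        intercept=True,
        min_n=4,
    )
    return PPLFERSystem(
        column_id=column_id,
        c=coefs["c"],
        e=coefs["e"],
        s=0.0,
        a=0.0,
        l=coefs["l"],
        stderr=ses,
        r2=r2,
        sd=sd,
        n=n,
    )


def calibrate_polar(refs: pd.DataFrame, column_id: str = "") -> PPLFERSystem:
    """Calibrate a polar column: RI = c + eE + sS + aA + lL.

    ``refs`` needs columns ``ri, E, S, A, L``; at least 6 compounds with
    variation in each used descriptor. Descriptors without variance are
    reported NaN (the fit then reduces to the remaining terms, e.g. to the
    nonpolar form when S and A are identically zero).
    """
    coefs, ses, r2, sd, n = _ols(
        refs["ri"].to_numpy(),
        {
            "e": refs["E"].to_numpy(),
            "s": refs["S"].to_numpy(),
            "a": refs["A"].to_numpy(),
            "l": refs["L"].to_numpy(),
        },
        intercept=True,
        min_n=6,
    )
    return PPLFERSystem(
        column_id=column_id,
        c=coefs["c"],
        e=coefs["e"],
        s=coefs["s"],
        a=coefs["a"],
        l=coefs["l"],
        stderr=ses,
        r2=r2,
        sd=sd,
        n=n,
    )


def derive_L(ri: float, E: float, system: PPLFERSystem) -> float:
    """CP L descriptor from its nonpolar-column RI: L = (RI - c - eE) / l."""
    if not system.is_nonpolar:
        raise ValueError(
            f"column {system.column_id!r} is polar (s or a nonzero); "
            "L must come from the nonpolar reference column"
        )
    if system.l == 0 or math.isnan(system.l):
        raise ZeroDivisionError("system parameter l is zero; L is undefined")
    e = 0.0 if math.isnan(system.e) else system.e
    return (float(ri) - system.c - e * float(E)) / system.l


@dataclass(frozen=True)
class SAResult:
    """Jointly derived S and A of one CP, with OLS standard errors."""

    S: float
    A: float
    se_S: float
    se_A: float
    n_columns: int
    column_ids: tuple[str, ...]


def derive_SA(
    cp_rows: Sequence[tuple[float, PPLFERSystem]],
    E: float,
    L: float,
    omit: Iterable[str] = (),
) -> SAResult:
    """Solve sS + aA = RI - c - eE - lL across polar columns, zero intercept.

    ``cp_rows`` pairs the compound's weighted-mean RI on each polar column
    with that column's calibrated system. Columns named in ``omit`` are
    excluded (e.g. drop the most polar column to probe robustness). Needs
    at least two columns with non-proportional (s, a); with exactly two the
    2x2 system is solved exactly and standard errors are undefined (NaN).
    """
    omit = set(omit)
    used = [(ri, sys) for ri, sys in cp_rows if sys.column_id not in omit]
    for _, sys in used:
        if sys.is_nonpolar:
            raise ValueError(
                f"column {sys.column_id!r} is nonpolar; only polar columns "
                "constrain S and A"
            )
    if len(used) < 2:
        raise UnidentifiableError(
            f"need >= 2 polar columns to separate S and A, got {len(used)}"
        )
    y = np.array(
        [
            ri
            - sys.c
            - (0.0 if math.isnan(sys.e) else sys.e) * E
            - sys.l * L
            for ri, sys in used
        ]
    )
    X = np.array([[sys.s, sys.a] for _, sys in used], dtype=float)
    if np.linalg.matrix_rank(X) < 2:
        raise UnidentifiableError(
            "polar columns have proportional (s, a) parameters; "
            "S and A are not separable"
        )
    res = sm.OLS(y, X).fit()
    se = res.bse if len(used) > 2 else np.array([np.nan, np.nan])
    return SAResult(
        S=float(res.params[0]),
        A=float(res.params[1]),
        se_S=float(se[0]),
        se_A=float(se[1]),
        n_columns=len(used),
        column_ids=tuple(sys.column_id for _, sys in used),
    )


def calibrate_columns(
    ref_descriptors: pd.DataFrame,
    ref_ri: pd.DataFrame,
    nonpolar_column: str,
) -> dict[str, PPLFERSystem]:
    """Calibrate every column found in a long-format reference RI table.

    ``ref_descriptors``: columns ``compound_id, E, S, A, L``;
    ``ref_ri``: columns ``compound_id, column_id, ri``. The named nonpolar
    column is fit with the reduced equation (s = a = 0), the rest with the
    full polar equation.
    """
    merged = ref_ri.merge(ref_descriptors, on="compound_id", how="inner")
    systems: dict[str, PPLFERSystem] = {}
    for col, grp in merged.groupby("column_id", sort=True):
        if col == nonpolar_column:
            systems[col] = calibrate_nonpolar(grp, column_id=col)
        else:
            systems[col] = calibrate_polar(grp, column_id=col)
    if nonpolar_column not in systems:
        raise ValueError(f"nonpolar column {nonpolar_column!r} absent from RI table")
    return systems


def derive_cp_descriptors(
    cp_ri: pd.DataFrame,
    systems: Mapping[str, PPLFERSystem],
    e_values: Mapping[str, float],
    nonpolar_column: str,
    omit: Iterable[str] = (),
) -> pd.DataFrame:
    """Full three-stage descriptor derivation for a table of CPs.

    ``cp_ri``: long format ``compound_id, column_id, ri`` (weighted-mean
    RIs, aggregation upstream); ``e_values``: externally estimated E per
    compound (E is an additive property taken as input, not fit here).
    Returns one row per compound with E, L, S, A, standard errors and the
    number of polar columns used. ``omit`` drops polar columns from the
    S/A stage only; L always comes from the nonpolar column.
    """
    nonpolar = systems[nonpolar_column]
    rows = []
    for cid, grp in cp_ri.groupby("compound_id", sort=True):
        by_col = dict(zip(grp["column_id"], grp["ri"]))
        if nonpolar_column not in by_col:
            raise ValueError(f"{cid!r} lacks an RI on the nonpolar column")
        E = float(e_values[cid])
        L = derive_L(by_col[nonpolar_column], E, nonpolar)
        polar_rows = [
            (ri, systems[col])
            for col, ri in by_col.items()
            if col != nonpolar_column and col in systems
        ]
        sa = derive_SA(polar_rows, E, L, omit=omit)
        rows.append(
            {
                "compound_id": cid,
                "E": E,
                "S": sa.S,
                "A": sa.A,
                "L": L,
                "se_S": sa.se_S,
                "se_A": sa.se_A,
                "n_polar_columns": sa.n_columns,
            }
        )
    return pd.DataFrame(rows)
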