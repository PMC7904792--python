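"""RI prediction from temperature-dependent air-polymer partition coefficients.

Quantum-chemical tools can predict the air-to-stationary-phase partition
coefficient K_air-polymer of an analyte at several temperatures. Because
log10 K is linear in 1/T (van't Hoff), a two-parameter regression per
compound

    log10 K(T) = slope / T + intercept

suffices. A compound is taken to elute when its log K(T) falls to a
column-specific characteristic value log K* (calibrated from measured
n-alkane retention), giving a hypothetical elution temperature

    T_elute = slope / (log K* - intercept).

During a linear oven ramp, time and temperature are affine, so T_elute is
interpolated between the n-alkane elution temperatures exactly as a
retention time would be, yielding a predicted RI. Diastereomers of one
congener are aggregated by the unweighted mean (and max - min range), and
a final empirical linear correction (measured = alpha * predicted + beta)
absorbs systematic column-specific bias.

All log K values are log10; natural-log inputs must be converted upstream.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import CalibrationError, NoCrossingError, OutOfRangeError
from .retention import AlkaneLadder, ltpri

__all__ = [
    "TemperatureProgram",
    "VantHoffFit",
    "ColumnElutionModel",
    "CorrectionResult",
    "fit_vant_hoff",
    "elution_temperature",
    "calibrate_characteristic_logK",
    "predicted_ri",
    "aggregate_diastereomers",
    "empirical_correction",
    "fit_logk_table",
    "predict_ri_table",
]


@dataclass(frozen=True)
class TemperatureProgram:
    """Linear GC oven program: hold at T0, ramp at a fixed rate, hold at Tmax.

    Temperatures in kelvin, times in minutes, rate in K/min.
    """

    t0_k: float
    hold0_min: float
    rate_k_per_min: float
    tmax_k: float
    holdf_min: float = 0.0

    def __post_init__(self) -> None:
        if self.t0_k <= 0 or self.tmax_k <= self.t0_k:
            raise ValueError("need 0 < T0 < Tmax")
        if self.rate_k_per_min <= 0:
            raise ValueError("ramp rate must be positive")
        if self.hold0_min < 0 or self.holdf_min < 0:
            raise ValueError("hold times must be non-negative")

    @classmethod
    def from_celsius(
        cls, t0_c: float, hold0_min: float, rate_c_per_min: float,
        tmax_c: float, holdf_min: float = 0.0,
    ) -> "TemperatureProgram":
        return cls(t0_c + 273.15, hold0_min, rate_c_per_min, tmax_c + 273.15, holdf_min)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "TemperatureProgram":
        """Build from flat keys ``T0_C, hold0_min, rate_C_per_min, Tmax_C, holdf_min``."""
        return cls.from_celsius(
            float(d["T0_C"]), float(d["hold0_min"]), float(d["rate_C_per_min"]),
            float(d["Tmax_C"]), float(d.get("holdf_min", 0.0)),
        )

    def temperature_at(self, rt_min: float) -> float:
        """Oven temperature at retention time ``rt_min`` (capped at Tmax)."""
        t = self.t0_k + self.rate_k_per_min * max(0.0, rt_min - self.hold0_min)
        return min(t, self.tmax_k)

    def time_at(self, temperature_k: float) -> float:
        """Retention time at which the ramp reaches ``temperature_k``."""
        if not (self.t0_k <= temperature_k <= self.tmax_k):
            raise OutOfRangeError(
                f"{temperature_k:g} K outside the program span "
                f"[{self.t0_k:g}, {self.tmax_k:g}] K"
            )
        return self.hold0_min + (temperature_k - self.t0_k) / self.rate_k_per_min


@dataclass(frozen=True)
class VantHoffFit:
    """log10 K = slope / T + intercept; slope in K·log-units."""

    slope: float
    intercept: float
    r2: float = float("nan")

    def logk_at(self, temperature_k: float) -> float:
        return self.slope / temperature_k + self.intercept


def fit_vant_hoff(
    temperatures_k: Sequence[float], logk: Sequence[float]
) -> VantHoffFit:
    """Least-squares van't Hoff regression of log10 K on 1/T.

    Needs at least two distinct positive temperatures; with exactly two
    points the line passes through both.
    """
    T = np.asarray(temperatures_k, dtype=float)
    y = np.asarray(logk, dtype=float)
    if len(T) != len(y) or len(T) < 2:
        raise ValueError("need >= 2 (temperature, logK) points")
    if (T <= 0).any():
        raise ValueError("temperatures must be positive kelvin")
    x = 1.0 / T
    if np.ptp(x) == 0.0:
        raise ValueError("all temperatures equal; the regression is singular")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return VantHoffFit(float(slope), float(intercept), r2)


@dataclass(frozen=True)
class ColumnElutionModel:
    """Everything needed to turn a van't Hoff fit into an RI on one column.

    ``alkane_temps`` are the n-alkane elution temperatures (kelvin, strictly
    increasing with carbon number), either predicted through the same
    partition pathway (default mode) or implied by measured retention times
    via the temperature program.
    """

    column_id: str
    program: TemperatureProgram
    characteristic_logk: float
    alkane_carbons: tuple[int, ...]
    alkane_temps: tuple[float, ...]

    def __post_init__(self) -> None:
        # AlkaneLadder validation covers monotonicity and length
        object.__setattr__(self, "alkane_carbons", tuple(int(n) for n in self.alkane_carbons))
        object.__setattr__(self, "alkane_temps", tuple(float(t) for t in self.alkane_temps))
        self.temperature_ladder()

    def temperature_ladder(self) -> AlkaneLadder:
        """The alkane reference expressed in the elution-temperature domain."""
        return AlkaneLadder(self.alkane_carbons, self.alkane_temps, self.column_id)


def _crossing_temperature(fit: VantHoffFit, characteristic_logk: float) -> float:
    """Unclamped temperature at which log K(T) equals the characteristic value."""
    if fit.slope == 0:
        raise NoCrossingError(
            "van't Hoff slope is 0: log K never crosses the characteristic value"
        )
    denom = characteristic_logk - fit.intercept
    if denom == 0:
        raise NoCrossingError("characteristic logK equals the intercept (T -> inf)")
    return fit.slope / denom


def elution_temperature(fit: VantHoffFit, model: ColumnElutionModel) -> float:
    """Hypothetical elution temperature of a compound on the column.

    The crossing T = slope / (logK* - intercept); values outside the ramp
    span indicate elution during a hold and are clamped to T0 or Tmax with
    a warning.
    """
    t = _crossing_temperature(fit, model.characteristic_logk)
    prog = model.program
    if t < prog.t0_k or t > prog.tmax_k:
        bound = prog.t0_k if t < prog.t0_k else prog.tmax_k
        warnings.warn(
            f"elution temperature {t:.1f} K falls outside the ramp of "
            f"{model.column_id or 'column'} [{prog.t0_k:.1f}, {prog.tmax_k:.1f}] K; "
            f"clamped to {bound:.1f} K (compound elutes during a hold)",
            stacklevel=2,
        )
        return bound
    return t


def calibrate_characteristic_logK(
    alkane_fits: Sequence[tuple[int, VantHoffFit]],
    ladder: AlkaneLadder,
    program: TemperatureProgram,
    xatol: float = 1e-9,
) -> float:
    """Column-specific log K* from measured n-alkane retention.

    Measured retention times imply elution temperatures through the ramp;
    log K* is the scalar minimising the squared mismatch between those and
    the crossings of each alkane's van't Hoff line, found by bounded 1-D
    minimisation over the span of alkane log K values at the program's
    temperature limits. A single alkane is solved exactly.
    """
    rt_by_n = dict(zip(ladder.carbon_numbers, ladder.retention_times))
    pairs = [(n, f) for n, f in alkane_fits if n in rt_by_n]
    if not pairs:
        raise CalibrationError("no alkane fit matches a ladder retention time")
    targets = np.array([program.temperature_at(rt_by_n[n]) for n, _ in pairs])
    if len(pairs) == 1:
        n, f = pairs[0]
        return f.logk_at(targets[0])
    lo = min(
        min(f.logk_at(program.t0_k), f.logk_at(program.tmax_k)) for _, f in pairs
    )
    hi = max(
        max(f.logk_at(program.t0_k), f.logk_at(program.tmax_k)) for _, f in pairs
    )
    if not (hi > lo):
        raise CalibrationError(
            "degenerate bracket: alkane logK values identical over the program span"
        )

    def objective(logk_star: float) -> float:
        try:
            ts = np.array([_crossing_temperature(f, logk_star) for _, f in pairs])
        except NoCrossingError:
            return np.inf
        return float(((ts - targets) ** 2).sum())

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    if not res.success or not np.isfinite(res.fun):
        raise CalibrationError("characteristic logK calibration did not converge")
    endpoint_best = min(objective(lo), objective(hi))
    if res.fun > endpoint_best + 1e-9 * (1.0 + endpoint_best):
        raise CalibrationError("no interior bracket: optimum worse than endpoints")
    return float(res.x)


def predicted_ri(
    fit: VantHoffFit, model: ColumnElutionModel, extrapolate: bool = False
) -> float:
    """Predicted RI: interpolate T_elute between alkane elution temperatures.

    Identical arithmetic to the retention-time RI because time and
    temperature are affine during the ramp; exact 100 * n when T_elute
    coincides with alkane n's elution temperature.
    """
    t = elution_temperature(fit, model)
    return ltpri(t, model.temperature_ladder(), extrapolate=extrapolate)


def aggregate_diastereomers(per_isomer_ri: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and range (max - min) of per-diastereomer RIs.

    The stereoisomer composition of a standard is unknown, so no isomer is
    weighted above another; a single isomer returns (value, 0).
    """
    values = [float(v) for v in per_isomer_ri]
    if not values:
        raise ValueError("no per-isomer RI values to aggregate")
    return float(np.mean(values)), float(max(values) - min(values))


@dataclass(frozen=True)
class CorrectionResult:
    """Affine correction measured = alpha * predicted + beta, with RMSEs."""

    alpha: float
    beta: float
    rmse_before: float
    rmse_after: float

    def apply(self, predicted: float | np.ndarray) -> float | np.ndarray:
        return self.alpha * np.asarray(predicted, dtype=float) + self.beta


def empirical_correction(
    pairs: Sequence[tuple[float, float]]
) -> CorrectionResult:
    """Fit the per-column bias correction from (predicted, measured) CP pairs.

    OLS of measured on predicted; because the identity line is in the model
    class, the corrected RMSE never exceeds the uncorrected one. Needs at
    least 3 pairs with varying predictions.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (predicted, measured) pairs")
    pred, meas = arr[:, 0], arr[:, 1]
    if np.ptp(pred) == 0.0:
        raise ValueError("all predicted RIs equal; the correction is singular")
    alpha, beta = np.polyfit(pred, meas, 1)
    rmse_before = float(np.sqrt(np.mean((meas - pred) ** 2)))
    corrected = alpha * pred + beta
    rmse_after = float(np.sqrt(np.mean((meas - corrected) ** 2)))
    return CorrectionResult(float(alpha), float(beta), rmse_before, rmse_after)


_ALKANE_ID = re.compile(r"^C(\d+)$")


def fit_logk_table(logk: pd.DataFrame) -> dict[tuple[str, str], VantHoffFit]:
    """Per-(compound, stereoisomer) van't Hoff fits from a long logK table.

    ``logk`` columns: ``compound_id, stereoisomer_id, T_K, logK10`` (the
    stereoisomer column may be empty for achiral compounds).
    """
    out: dict[tuple[str, str], VantHoffFit] = {}
    iso = logk["stereoisomer_id"].fillna("") if "stereoisomer_id" in logk else ""
    df = logk.assign(stereoisomer_id=iso)
    for (cid, sid), grp in df.groupby(["compound_id", "stereoisomer_id"], sort=True):
        out[(str(cid), str(sid))] = fit_vant_hoff(
            grp["T_K"].to_numpy(), grp["logK10"].to_numpy()
        )
    return out


def predict_ri_table(
    logk: pd.DataFrame,
    program: TemperatureProgram,
    characteristic_logk: float | None = None,
    measured_ladder: AlkaneLadder | None = None,
    column_id: str = "",
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Predict per-congener RIs from a logK(T) table containing n-alkanes.

    Rows whose ``compound_id`` matches ``C<n>`` are treated as the n-alkane
    references: their fits provide the alkane elution temperatures
    (predicted-alkane mode) and — together with ``measured_ladder`` — the
    characteristic log K* when it is not supplied. Returns one row per
    compound: ``compound_id, n_isomers, ri_mean, ri_range``.
    """
    fits = fit_logk_table(logk)
    alkane_fits: list[tuple[int, VantHoffFit]] = []
    analyte_fits: dict[str, dict[str, VantHoffFit]] = {}
    for (cid, sid), fit in fits.items():
        m = _ALKANE_ID.match(cid)
        if m is not None:
            alkane_fits.append((int(m.group(1)), fit))
        else:
            analyte_fits.setdefault(cid, {})[sid] = fit
    if not alkane_fits:
        raise ValueError("logK table contains no n-alkane rows (compound_id 'C<n>')")
    alkane_fits.sort()
    if characteristic_logk is None:
        if measured_ladder is None:
            raise ValueError(
                "supply characteristic_logk or a measured alkane ladder to calibrate it"
            )
        characteristic_logk = calibrate_characteristic_logK(
            alkane_fits, measured_ladder, program
        )
    temps = [_crossing_temperature(f, characteristic_logk) for _, f in alkane_fits]
    model = ColumnElutionModel(
        column_id=column_id,
        program=program,
        characteristic_logk=characteristic_logk,
        alkane_carbons=tuple(n for n, _ in alkane_fits),
        alkane_temps=tuple(temps),
    )
    rows = []
    for cid, by_iso in sorted(analyte_fits.items()):
        ris = [predicted_ri(f, model, extrapolate=extrapolate) for f in by_iso.values()]
        mean, rng = aggregate_diastereomers(ris)
        rows.append(
            {
                "compound_id": cid,
                "column_id": column_id,
                "n_isomers": len(ris),
                "ri_mean": mean,
                "ri_range": rng,
            }
        )
    return pd.DataFrame(rows)
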