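"""Synthetic pipeline inputs with known ground truth.

No measured CP retention tables are publicly deposited, so every stage of
the package is exercised against generated data whose ground truth is held
alongside: six GC columns of graded polarity with known ppLFER system
parameters, a reference-compound set (n-alkanes plus alcohol/ester/PAH-like
solutes), CP congener peak tables whose diastereomer peaks spread more on
more polar columns, and logK(T) tables constructed so that the elution
round trip returns prescribed RIs.

Two constraints shape the truth model:

* n-alkanes define the RI scale on every column (RI = 100 * n by
  definition), and alkane solutes have E = S = A = 0. Consistency of the
  ppLFER truth with the RI definition therefore forces a shared c and l
  across columns: alkane L values follow L_n = (100 n - c) / l. With
  c = 71 and l = 198 this reproduces the Abraham alkane pattern
  (L(C10) = 4.69, increment ~0.505 per CH2). Columns differ in e, s, a.
* Noise is Gaussian on reference-compound RIs only; CP per-isomer RIs are
  the true congener mean plus a deterministic centered spread (scaled by a
  per-column polarity multiplier), so descriptor-recovery error is fully
  attributable to calibration noise and the spread is exactly controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .congener import Congener, parse_congener
from .pplfer import PPLFERSystem
from .prediction import (
    ColumnElutionModel,
    TemperatureProgram,
    _crossing_temperature,
)
from .retention import AlkaneLadder, PeakTable, inverse_ltpri
from .stereo import enumerate_diastereomers

__all__ = [
    "ColumnSpec",
    "GeneratorConfig",
    "ReferenceSet",
    "CPPeakData",
    "LogKData",
    "DEFAULT_COLUMNS",
    "alkane_L",
    "make_reference_set",
    "make_cp_peaks",
    "make_logk_tables",
    "write_dataset",
]

#: shared truth intercept and L coefficient (see module docstring)
C_TRUTH = 71.0
L_COEF_TRUTH = 198.0


def alkane_L(n_carbons: int | np.ndarray) -> float | np.ndarray:
    """True L of an n-alkane under the generator's ppLFER truth model."""
    return (100.0 * np.asarray(n_carbons, dtype=float) - C_TRUTH) / L_COEF_TRUTH


@dataclass(frozen=True)
class ColumnSpec:
    """Ground-truth description of one synthetic GC column."""

    column_id: str
    e: float
    s: float
    a: float
    polarity_rank: int
    program: TemperatureProgram
    c: float = C_TRUTH
    l: float = L_COEF_TRUTH
    characteristic_logk: float = 2.0

    def system(self) -> PPLFERSystem:
        """The true ppLFER system (no fit diagnostics)."""
        return PPLFERSystem(
            column_id=self.column_id, c=self.c, e=self.e, s=self.s,
            a=self.a, l=self.l,
        )

    def true_ri(self, E: float, S: float, A: float, L: float) -> float:
        return self.c + self.e * E + self.s * S + self.a * A + self.l * L


# Six columns of graded polarity with the oven programs used in practice
# for each phase type; the nonpolar octyl phase anchors the scale (s=a=0).
DEFAULT_COLUMNS: tuple[ColumnSpec, ...] = (
    ColumnSpec("SPB-Octyl", e=20.0, s=0.0, a=0.0, polarity_rank=0,
               program=TemperatureProgram.from_celsius(70, 1.0, 10, 280, 10)),
    ColumnSpec("HP-5ms", e=40.0, s=30.0, a=25.0, polarity_rank=1,
               program=TemperatureProgram.from_celsius(70, 0.1, 10, 280, 10)),
    ColumnSpec("DB-17ms", e=90.0, s=120.0, a=90.0, polarity_rank=2,
               program=TemperatureProgram.from_celsius(60, 1.0, 10, 300, 10)),
    ColumnSpec("InertCap-17ms", e=100.0, s=140.0, a=110.0, polarity_rank=3,
               program=TemperatureProgram.from_celsius(70, 1.0, 20, 300, 10)),
    ColumnSpec("DB-225ms", e=60.0, s=260.0, a=330.0, polarity_rank=4,
               program=TemperatureProgram.from_celsius(70, 0.1, 10, 240, 15)),
    ColumnSpec("SolGel-WAX", e=150.0, s=320.0, a=450.0, polarity_rank=5,
               program=TemperatureProgram.from_celsius(70, 1.0, 10, 280, 5)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    ``ri_noise_sd`` is the Gaussian SD (RI units) added to reference
    RIs; descriptor ranges are uniform sampling bounds on the Abraham
    scales; ``diastereomer_spread`` is the base per-congener RI spread on
    the nonpolar column, multiplied by ``polarity_multiplier **
    polarity_rank`` on more polar columns.
    """

    seed: int = 0
    n_reference_compounds: int = 40
    n_alkane_refs: int = 10
    ri_noise_sd: float = 20.0
    e_range: tuple[float, float] = (0.0, 2.5)
    s_range: tuple[float, float] = (0.0, 1.3)
    a_range: tuple[float, float] = (0.0, 0.6)
    l_range: tuple[float, float] = (3.5, 10.5)
    cp_e_range: tuple[float, float] = (0.3, 1.0)
    cp_s_range: tuple[float, float] = (0.4, 1.2)
    cp_a_range: tuple[float, float] = (0.0, 0.35)
    cp_l_range: tuple[float, float] = (5.0, 9.5)
    alkane_carbons: tuple[int, ...] = tuple(range(7, 36))
    columns: tuple[ColumnSpec, ...] = DEFAULT_COLUMNS
    diastereomer_spread: float = 40.0
    polarity_multiplier: float = 1.3
    vant_hoff_slope_range: tuple[float, float] = (3000.0, 6000.0)
    logk_temperatures: tuple[float, ...] = (373.15, 423.15, 473.15, 523.15, 573.15)

    def __post_init__(self) -> None:
        if self.ri_noise_sd < 0:
            raise ValueError("ri_noise_sd must be >= 0")
        for name in ("e_range", "s_range", "a_range", "l_range",
                     "cp_e_range", "cp_s_range", "cp_a_range", "cp_l_range",
                     "vant_hoff_slope_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"degenerate range {name}: ({lo}, {hi})")
        if self.n_alkane_refs > self.n_reference_compounds:
            raise ValueError("n_alkane_refs exceeds n_reference_compounds")
        if len(self.alkane_carbons) < 2:
            raise ValueError("need at least 2 ladder alkanes")
        if self.diastereomer_spread < 0:
            raise ValueError("diastereomer_spread must be >= 0")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def column(self, column_id: str) -> ColumnSpec:
        for col in self.columns:
            if col.column_id == column_id:
                return col
        raise KeyError(column_id)


def make_alkane_ladder(col: ColumnSpec, carbons: Sequence[int]) -> AlkaneLadder:
    """Measured-style ladder: alkane elution temperatures spread affinely
    over the ramp interior (a boiling-point-like map of carbon number),
    then converted to retention times through the program."""
    prog = col.program
    carbons = sorted(int(n) for n in carbons)
    n_lo, n_hi = carbons[0], carbons[-1]
    span = prog.tmax_k - prog.t0_k
    temps = [
        prog.t0_k + span * (n - n_lo + 1) / (n_hi - n_lo + 2) for n in carbons
    ]
    rts = [prog.time_at(t) for t in temps]
    return AlkaneLadder(tuple(carbons), tuple(rts), column_id=col.column_id)


@dataclass(frozen=True)
class ReferenceSet:
    """Reference-compound descriptors, per-column RIs and the truth systems."""

    descriptors: pd.DataFrame  # compound_id, E, S, A, B, L
    ri: pd.DataFrame  # compound_id, column_id, ri
    systems: dict[str, PPLFERSystem]  # ground truth


def make_reference_set(cfg: GeneratorConfig) -> ReferenceSet:
    """Draw the calibration set and its per-column RIs.

    The first ``n_alkane_refs`` compounds are n-alkanes (E = S = A = 0,
    L on the truth line, hence RI exactly 100 n at zero noise); the rest
    draw each descriptor uniformly from the configured range. Gaussian
    noise of SD ``ri_noise_sd`` is added independently per (compound,
    column) RI.
    """
    rng = cfg.rng(salt=1)
    step = max(1, len(cfg.alkane_carbons) // max(cfg.n_alkane_refs, 1))
    alk = list(cfg.alkane_carbons)[::step][: cfg.n_alkane_refs]
    rows = [
        {"compound_id": f"C{n}", "E": 0.0, "S": 0.0, "A": 0.0, "B": 0.0,
         "L": float(alkane_L(n))}
        for n in alk
    ]
    n_other = cfg.n_reference_compounds - len(rows)
    for i in range(n_other):
        rows.append(
            {
                "compound_id": f"ref{i:03d}",
                "E": float(rng.uniform(*cfg.e_range)),
                "S": float(rng.uniform(*cfg.s_range)),
                "A": float(rng.uniform(*cfg.a_range)),
                "B": 0.0,
                "L": float(rng.uniform(*cfg.l_range)),
            }
        )
    desc = pd.DataFrame(rows)
    ri_rows = []
    for col in cfg.columns:
        noise = rng.normal(0.0, cfg.ri_noise_sd, size=len(desc)) if cfg.ri_noise_sd > 0 else np.zeros(len(desc))
        for (_, r), eps in zip(desc.iterrows(), noise):
            ri_rows.append(
                {
                    "compound_id": r["compound_id"],
                    "column_id": col.column_id,
                    "ri": col.true_ri(r["E"], r["S"], r["A"], r["L"]) + float(eps),
                }
            )
    systems = {col.column_id: col.system() for col in cfg.columns}
    return ReferenceSet(desc, pd.DataFrame(ri_rows), systems)


def _cp_descriptors(congeners: Sequence[Congener], cfg: GeneratorConfig) -> pd.DataFrame:
    rng = cfg.rng(salt=2)
    rows = []
    for c in congeners:
        rows.append(
            {
                "compound_id": c.name,
                "E": float(rng.uniform(*cfg.cp_e_range)),
                "S": float(rng.uniform(*cfg.cp_s_range)),
                "A": float(rng.uniform(*cfg.cp_a_range)),
                "B": float("nan"),
                "L": float(rng.uniform(*cfg.cp_l_range)),
            }
        )
    return pd.DataFrame(rows)


def _centered_offsets(k: int) -> np.ndarray:
    """Deterministic centered spread pattern in [-1/2, 1/2], mean zero."""
    if k == 1:
        return np.zeros(1)
    return np.linspace(-0.5, 0.5, k)


@dataclass(frozen=True)
class CPPeakData:
    """Per-column peak tables and ladders for CP congeners, plus ground truth.

    ``truth`` has one row per (congener, column): the true mean RI, the
    area-weighted mean implied by the generated peaks, and the per-isomer
    spread applied; ``isomer_truth`` one row per (congener, stereoisomer,
    column) with the exact per-isomer RI.
    """

    peaks: dict[str, PeakTable]
    ladders: dict[str, AlkaneLadder]
    truth: pd.DataFrame
    isomer_truth: pd.DataFrame
    descriptors: pd.DataFrame


def make_cp_peaks(
    congeners: Sequence[Congener | str],
    cfg: GeneratorConfig,
    max_isomers: int | None = None,
) -> CPPeakData:
    """Generate multi-peak CP standards on every configured column.

    Each congener produces one peak per diastereomer (optionally capped at
    ``max_isomers`` to mimic standards containing only a few stereoisomers).
    Per-isomer RIs are the congener's true ppLFER RI plus a deterministic
    centered offset scaled by ``diastereomer_spread *
    polarity_multiplier**rank``; retention times are back-computed through
    the ladder so LTPRI recovers those RIs exactly; areas are positive
    lognormal draws.
    """
    congeners = [c if isinstance(c, Congener) else parse_congener(c) for c in congeners]
    desc = _cp_descriptors(congeners, cfg)
    rng = cfg.rng(salt=3)
    peaks: dict[str, PeakTable] = {}
    ladders: dict[str, AlkaneLadder] = {}
    truth_rows, isomer_rows = [], []
    reps_by_congener = {
        c.name: enumerate_diastereomers(c)[: max_isomers or None] for c in congeners
    }
    areas_by_congener = {
        name: rng.lognormal(mean=0.0, sigma=0.5, size=len(reps))
        for name, reps in reps_by_congener.items()
    }
    for col in cfg.columns:
        ladder = make_alkane_ladder(col, cfg.alkane_carbons)
        ladders[col.column_id] = ladder
        spread = cfg.diastereomer_spread * cfg.polarity_multiplier**col.polarity_rank
        rows = []
        for c, (_, d) in zip(congeners, desc.iterrows()):
            reps = reps_by_congener[c.name]
            base = col.true_ri(d["E"], d["S"], d["A"], d["L"])
            offsets = _centered_offsets(len(reps))
            areas = areas_by_congener[c.name]
            ris = base + spread * offsets
            for rep, ri, area in zip(reps, ris, areas):
                rows.append(
                    {
                        "compound_id": c.name,
                        "peak_id": rep.stereoisomer_id,
                        "rt_min": inverse_ltpri(ri, ladder),
                        "area": float(area),
                    }
                )
                isomer_rows.append(
                    {
                        "compound_id": c.name,
                        "stereoisomer_id": rep.stereoisomer_id,
                        "column_id": col.column_id,
                        "ri": float(ri),
                    }
                )
            truth_rows.append(
                {
                    "compound_id": c.name,
                    "column_id": col.column_id,
                    "true_mean_ri": float(base),
                    "weighted_mean_ri": float((ris * areas).sum() / areas.sum()),
                    "spread": float(spread) if len(reps) > 1 else 0.0,
                    "n_isomers": len(reps),
                }
            )
        peaks[col.column_id] = PeakTable(pd.DataFrame(rows), column_id=col.column_id)
    return CPPeakData(
        peaks=peaks,
        ladders=ladders,
        truth=pd.DataFrame(truth_rows),
        isomer_truth=pd.DataFrame(isomer_rows),
        descriptors=desc,
    )


@dataclass(frozen=True)
class LogKData:
    """Per-column logK(T) tables and elution models consistent with targets."""

    tables: dict[str, pd.DataFrame]  # compound_id, stereoisomer_id, T_K, logK10
    models: dict[str, ColumnElutionModel]
    targets: pd.DataFrame  # compound_id, stereoisomer_id, column_id, target_ri


def make_logk_tables(targets: pd.DataFrame, cfg: GeneratorConfig) -> LogKData:
    """Construct van't Hoff-consistent logK tables hitting prescribed RIs.

    ``targets`` columns: ``compound_id, stereoisomer_id, column_id,
    target_ri`` (stereoisomer may be empty). For every row a slope is drawn
    from ``vant_hoff_slope_range`` and the intercept solved so that the
    crossing of the characteristic log K* occurs at the elution temperature
    whose interpolated RI equals the target. Alkane rows (one per ladder
    carbon, target 100 n) are appended per column; target RIs must lie
    within the alkane span.
    """
    rng = cfg.rng(salt=4)
    grid = np.asarray(cfg.logk_temperatures, dtype=float)
    tables: dict[str, pd.DataFrame] = {}
    models: dict[str, ColumnElutionModel] = {}
    target_rows = []
    for col in cfg.columns:
        ladder = make_alkane_ladder(col, cfg.alkane_carbons)
        temps = tuple(
            col.program.temperature_at(rt) for rt in ladder.retention_times
        )
        temp_ladder = AlkaneLadder(ladder.carbon_numbers, temps, col.column_id)
        model = ColumnElutionModel(
            column_id=col.column_id,
            program=col.program,
            characteristic_logk=col.characteristic_logk,
            alkane_carbons=ladder.carbon_numbers,
            alkane_temps=temps,
        )
        models[col.column_id] = model
        rows = []

        def _emit(cid: str, sid: str, target_ri: float) -> None:
            t_elute = inverse_ltpri(target_ri, temp_ladder)
            slope = float(rng.uniform(*cfg.vant_hoff_slope_range))
            intercept = col.characteristic_logk - slope / t_elute
            for T in grid:
                rows.append(
                    {
                        "compound_id": cid,
                        "stereoisomer_id": sid,
                        "T_K": float(T),
                        "logK10": slope / float(T) + intercept,
                    }
                )
            target_rows.append(
                {
                    "compound_id": cid,
                    "stereoisomer_id": sid,
                    "column_id": col.column_id,
                    "target_ri": float(target_ri),
                }
            )

        for n in ladder.carbon_numbers:
            _emit(f"C{n}", "", 100.0 * n)
        sel = targets[targets["column_id"] == col.column_id]
        for _, r in sel.iterrows():
            sid = r.get("stereoisomer_id", "") or ""
            _emit(str(r["compound_id"]), str(sid), float(r["target_ri"]))
        tables[col.column_id] = pd.DataFrame(rows)
    return LogKData(tables=tables, models=models, targets=pd.DataFrame(target_rows))


def write_dataset(
    outdir: str | Path,
    cfg: GeneratorConfig,
    congeners: Sequence[Congener | str],
    max_isomers: int | None = None,
) -> dict[str, Path]:
    """Generate and write the full synthetic study to ``outdir`` as CSV/JSON.

    Emits reference descriptors and RIs, truth system parameters, per-column
    peak tables, ladders and logK tables, and a flat ``truth.json``. Output
    is byte-identical for identical configs (fixed seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = path

    refs = make_reference_set(cfg)
    _write("reference_descriptors.csv", refs.descriptors)
    _write("reference_ri.csv", refs.ri)
    _write(
        "systems_truth.csv",
        pd.DataFrame(
            [
                {"column_id": s.column_id, "c": s.c, "e": s.e, "s": s.s,
                 "a": s.a, "b": s.b, "l": s.l}
                for s in refs.systems.values()
            ]
        ),
    )
    cp = make_cp_peaks(congeners, cfg, max_isomers=max_isomers)
    _write("cp_descriptors_truth.csv", cp.descriptors)
    _write("cp_ri_truth.csv", cp.truth)
    for col_id, table in cp.peaks.items():
        _write(f"peaks_{col_id}.csv", table.data)
    for col_id, ladder in cp.ladders.items():
        _write(f"ladder_{col_id}.csv", ladder.to_frame())
    logk = make_logk_tables(
        cp.isomer_truth.rename(columns={"ri": "target_ri"}), cfg
    )
    for col_id, df in logk.tables.items():
        _write(f"logk_{col_id}.csv", df)
    truth = {
        "seed": cfg.seed,
        "columns": [
            {"column_id": c.column_id, "c": c.c, "e": c.e, "s": c.s, "a": c.a,
             "l": c.l, "polarity_rank": c.polarity_rank,
             "characteristic_logk": c.characteristic_logk}
            for c in cfg.columns
        ],
        "congeners": [
            c.name if isinstance(c, Congener) else parse_congener(c).name
            for c in congeners
        ],
    }
    path = outdir / "truth.json"
    path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    written["truth.json"] = path
    return written
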