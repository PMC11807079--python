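"""Prediction-error evaluation of brainECF predictions.

The accuracy metric is the symmetrized relative error

    PE = (Y_pred - Y_obs) / ((Y_pred + Y_obs) / 2),

bounded in (-2, 2) and antisymmetric under swapping prediction and
observation.  A k-fold discrepancy maps to |PE| = 2(k-1)/(k+1); the
conventional twofold acceptance band is |median PE| <= 2/3 (displayed as
0.67).  Predictions are evaluated at the exact observation times using
the simulator's dense output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .ivive import ClearanceSet, ExpressionRecord, TranswellRecord, build_clearance_set
from .model import CNSModelSpec, SimulationResult, simulate_brain_ecf

__all__ = [
    "TWOFOLD_PE",
    "ObservationSeries",
    "PEReport",
    "PredictionBand",
    "prediction_error",
    "fold_threshold",
    "median_pe",
    "fold_class",
    "evaluate_predictions",
    "bandwidth_predictions",
    "summarize_within_twofold",
]

TWOFOLD_PE = 2.0 / 3.0  # exact twofold bound; 0.67 is display rounding

OBS_COLUMNS = ("animal_id", "time_min", "conc_ng_per_mL")


@dataclass
class ObservationSeries:
    """Unbound brainECF concentration observations for one drug/regimen.

    ``data`` holds columns (animal_id, time_min, conc_ng_per_mL);
    concentrations must be strictly positive (PE is undefined at 0).
    """

    drug: str
    regimen_class: str
    data: pd.DataFrame
    provenance: str = "real"

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation data missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("observation series is empty")
        if (self.data["conc_ng_per_mL"] <= 0).any():
            raise ValueError("observed concentrations must be strictly positive")
        if (self.data["time_min"] < 0).any():
            raise ValueError("observation times must be non-negative")
        if self.provenance not in ("real", "synthetic"):
            raise ValueError("provenance must be 'real' or 'synthetic'")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_min"].to_numpy(dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["conc_ng_per_mL"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, drug: str = "", regimen_class: str = "short",
                 provenance: str = "real") -> "ObservationSeries":
        return cls(drug, regimen_class, pd.read_csv(path), provenance)


@dataclass
class PEReport:
    """Per-observation prediction errors plus summary for one scenario."""

    pe_values: np.ndarray
    median_pe: float
    fold_class: str
    keys: Dict[str, str] = field(default_factory=dict)
    per_animal_median: Optional[pd.Series] = None

    def within_twofold(self) -> bool:
        return abs(self.median_pe) <= TWOFOLD_PE


@dataclass
class PredictionBand:
    """Envelope of brainECF predictions over in vitro expression extremes.

    The upper curve comes from the *highest* in vitro expression (lowest
    REF, least efflux); a single reported expression value degenerates
    the band to one curve.
    """

    time: np.ndarray
    lower: np.ndarray
    central: np.ndarray
    upper: np.ndarray
    levels: Dict[str, float]

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.central + 1e-12)
                and np.all(self.central <= self.upper + 1e-12)):
            raise ValueError("band must be ordered lower <= central <= upper pointwise")


def prediction_error(y_pred: float, y_obs: float) -> float:
    """Symmetrized prediction error, bounded in (-2, 2)."""
    if y_pred < 0 or y_obs <= 0:
        raise ValueError("y_pred must be >= 0 and y_obs > 0")
    return (y_pred - y_obs) / ((y_pred + y_obs) / 2.0)


def fold_threshold(k: float) -> float:
    """|PE| magnitude corresponding to a k-fold discrepancy: 2(k-1)/(k+1)."""
    if k < 1:
        raise ValueError("fold k must be >= 1")
    return 2.0 * (k - 1.0) / (k + 1.0)


_FOLD_EDGES = [(2.0, "<2-fold"), (3.0, "<3-fold"), (5.0, "<5-fold")]


def fold_class(median_pe_value: float) -> str:
    """Classify |median PE| into half-open fold bands [t_k, t_{k+1})."""
    mag = abs(median_pe_value)
    for k, label in _FOLD_EDGES:
        if mag < fold_threshold(k):
            return label
    return ">=5-fold"


def median_pe(
    predictions: np.ndarray,
    observations: ObservationSeries,
    per_animal: bool = False,
) -> float:
    """Median of per-observation PEs, pooled across animals by default.

    ``predictions`` must align row-by-row with the observation table
    (model evaluated at the exact observation times).  With
    ``per_animal=True`` the median of per-animal medians is returned.
    """
    predictions = np.asarray(predictions, dtype=float)
    obs = observations.concentrations
    if predictions.shape != obs.shape:
        raise ValueError("predictions must align with the observation rows")
    if obs.size == 0:
        raise ValueError("no observations to evaluate")
    pes = np.array([prediction_error(p, o) for p, o in zip(predictions, obs)])
    if per_animal:
        df = observations.data.assign(pe=pes)
        return float(df.groupby("animal_id")["pe"].median().median())
    return float(np.median(pes))


def evaluate_predictions(
    result: SimulationResult,
    observations: ObservationSeries,
    keys: Optional[Dict[str, str]] = None,
    per_animal: bool = False,
) -> PEReport:
    """Score a simulation against observations at their exact times."""
    preds = result.ecf_at(observations.times)
    obs = observations.concentrations
    pes = np.array([prediction_error(p, o) for p, o in zip(preds, obs)])
    df = observations.data.assign(pe=pes)
    animal_medians = df.groupby("animal_id")["pe"].median()
    med = float(animal_medians.median()) if per_animal else float(np.median(pes))
    return PEReport(
        pe_values=pes,
        median_pe=med,
        fold_class=fold_class(med),
        keys=dict(keys or {}),
        per_animal_median=animal_medians,
    )


def bandwidth_predictions(
    spec_template: CNSModelSpec,
    record: TranswellRecord,
    expression_records: Sequence[ExpressionRecord],
    expr_in_vivo: float,
    grid: np.ndarray,
    no_ref: bool = False,
) -> PredictionBand:
    """Simulate once per reported in vitro expression level.

    Higher in vitro expression gives a lower REF, hence lower CL_Pgp and
    a *higher* predicted brainECF curve; the envelope is therefore
    ordered with the highest-expression curve on top.  With ``no_ref``
    (REF = 1) the band collapses to a single expression-independent
    curve.
    """
    phys = spec_template.physiology
    if no_ref:
        cl = build_clearance_set(record, phys.sa_bbb, phys.sa_bbb_trans, no_ref=True)
        res = simulate_brain_ecf(replace(spec_template, clearances=cl), grid)
        return PredictionBand(res.time, res.c_ecf, res.c_ecf, res.c_ecf, {"no_ref": 1.0})
    if len(expression_records) == 0:
        raise ValueError("at least one expression record is required")
    curves: Dict[str, np.ndarray] = {}
    levels: Dict[str, float] = {}
    for expr in expression_records:
        cl = build_clearance_set(
            record, phys.sa_bbb, phys.sa_bbb_trans,
            expr_in_vivo=expr_in_vivo, expression=expr,
        )
        res = simulate_brain_ecf(replace(spec_template, clearances=cl), grid)
        curves[expr.level] = res.c_ecf
        levels[expr.level] = expr.expression
    stacked = np.vstack(list(curves.values()))
    central = curves.get("average", stacked[0])
    return PredictionBand(
        time=np.asarray(grid, dtype=float),
        lower=stacked.min(axis=0),
        central=central,
        upper=stacked.max(axis=0),
        levels=levels,
    )


def summarize_within_twofold(
    reports: Sequence[PEReport], stratify_by: Sequence[str]
) -> pd.DataFrame:
    """Fraction of scenarios with |median PE| <= 2/3 per stratum.

    ``stratify_by`` names keys present on every report (e.g. drug,
    cell_line, expression_level, regimen).  Returns a table with the
    stratum keys, n, n_within and percent_within.
    """
    if len(reports) == 0:
        raise ValueError("no reports to summarize")
    stratify_by = list(stratify_by)
    rows = []
    for rep in reports:
        missing = [k for k in stratify_by if k not in rep.keys]
        if missing:
            raise KeyError(f"report missing stratification keys: {missing}")
        rows.append({**{k: rep.keys[k] for k in stratify_by},
                     "within": abs(rep.median_pe) <= TWOFOLD_PE})
    df = pd.DataFrame(rows)
    if not stratify_by:
        grouped = pd.DataFrame(
            {"n": [len(df)], "n_within": [int(df["within"].sum())]}
        )
    else:
        grouped = (
            df.groupby(stratify_by, sort=False)["within"]
            .agg(n="count", n_within="sum")
            .reset_index()
        )
    grouped["n_within"] = grouped["n_within"].astype(int)
    grouped["percent_within"] = 100.0 * grouped["n_within"] / grouped["n"]
    return grouped
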