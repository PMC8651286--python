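"""Spike-in mixture design and linear recovery calibration.

Leukocyte DNA diluted into an immune-null background at known proportions
gives per-cell-type expected fractions; ordinary least squares of observed
on expected yields a recovery slope used as the calibration divisor
(intercept is reported as a QC metric, not subtracted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .quantify import CalibrationTable


@dataclass(frozen=True)
class MixturePoint:
    point_id: str
    leukocyte_fraction: float
    composition: Mapping[str, float]  # per-cell-type fractions, sum to 1

    def __post_init__(self) -> None:
        if not (0 <= self.leukocyte_fraction <= 1):
            raise ValueError(f"{self.point_id}: leukocyte_fraction not in "
                             "[0, 1]")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.point_id}: composition sums to {total}")


@dataclass(frozen=True)
class MixtureDesign:
    points: tuple[MixturePoint, ...]
    background: str = "HEK-293"


#: Typical leukocyte composition used by the default dilution series.
DEFAULT_COMPOSITION: dict[str, float] = {
    "neutrophil": 0.55, "t_cell": 0.20, "monocyte": 0.10, "b_cell": 0.08,
    "eosinophil": 0.04, "cd8_t_cell": 0.02, "treg": 0.01,
}


def default_design(
        leukocyte_fractions: Sequence[float] = (1.0, 0.5, 0.25, 0.1, 0.05),
        composition: Mapping[str, float] | None = None) -> MixtureDesign:
    """Dilution series spanning down to 20-fold (5% leukocyte DNA)."""
    comp = dict(composition or DEFAULT_COMPOSITION)
    points = tuple(
        MixturePoint(f"mix_{int(round(f * 100))}", f, comp)
        for f in leukocyte_fractions)
    return MixtureDesign(points=points)


def expected_fractions(design: MixtureDesign) -> pd.DataFrame:
    """expected(cell type, point) = leukocyte fraction x composition."""
    rows = {
        p.point_id: {ct: p.leukocyte_fraction * c
                     for ct, c in p.composition.items()}
        for p in design.points
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class RecoveryFit:
    cell_type: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_recovery(expected: Sequence[float], observed: Sequence[float],
                 cell_type: str = "") -> RecoveryFit:
    """Ordinary least squares of observed on expected fractions."""
    if len(expected) != len(observed) or len(expected) < 2:
        raise ValueError("need >= 2 paired points")
    if len(set(map(float, expected))) < 2:
        raise ValueError("expected values are degenerate (all equal)")
    res = stats.linregress(expected, observed)
    return RecoveryFit(cell_type=cell_type, slope=float(res.slope),
                       intercept=float(res.intercept),
                       r_squared=float(res.rvalue) ** 2,
                       n_points=len(expected))


def derive_coefficients(fits: Mapping[str, RecoveryFit]) -> CalibrationTable:
    """Calibration divisor per cell type = fitted recovery slope."""
    coefficients: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for cell_type, fit in fits.items():
        if fit.slope <= 0:
            raise ValueError(
                f"non-positive recovery slope for {cell_type}: {fit.slope}")
        coefficients[cell_type] = fit.slope
        provenance[cell_type] = (
            f"spike-in fit: slope={fit.slope:.4f} "
            f"intercept={fit.intercept:.4f} r2={fit.r_squared:.4f} "
            f"n={fit.n_points}")
    return CalibrationTable(coefficients=coefficients, provenance=provenance)


def load_design(path: str | Path) -> MixtureDesign:
    """Design TSV: point_id, leukocyte_fraction, then composition columns."""
    df = pd.read_csv(path, sep="\t")
    comp_cols = [c for c in df.columns
                 if c not in ("point_id", "leukocyte_fraction")]
    points = tuple(
        MixturePoint(str(r["point_id"]), float(r["leukocyte_fraction"]),
                     {c: float(r[c]) for c in comp_cols})
        for _, r in df.iterrows())
    return MixtureDesign(points=points)
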