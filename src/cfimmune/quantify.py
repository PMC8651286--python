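"""Calibrated per-cell-type fractions and genome equivalents per ml.

A cell type's raw fraction is the unweighted mean of its markers'
fully-unmethylated fractions (read-weighted pooling available by config),
divided by a per-cell-type calibration coefficient, then scaled by the
sample's cfDNA concentration and the genomes-per-ng constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .constants import GENOMES_PER_NG, NEUTROPHIL_DIVISOR
from .panel import Panel
from .readcall import MarkerCount


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    donor_id: str = ""
    timepoint: str = ""
    group: str = ""
    cfdna_conc: float | None = None  # ng per ml plasma

    def __post_init__(self) -> None:
        if self.cfdna_conc is not None and self.cfdna_conc < 0:
            raise ValueError(f"{self.sample_id}: cfdna_conc must be >= 0")


@dataclass
class CalibrationTable:
    """Per-cell-type divisors applied to raw fractions.

    Cell types absent from the table get coefficient 1.0. Provenance notes
    travel with each coefficient for reporting.
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ct, c in self.coefficients.items():
            if c <= 0:
                raise ValueError(f"coefficient for {ct} must be > 0, got {c}")

    def coefficient(self, cell_type: str) -> float:
        return self.coefficients.get(cell_type, 1.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        notes = (dict(zip(df["cell_type"], df["provenance"]))
                 if "provenance" in df.columns else {})
        return cls(dict(zip(df["cell_type"],
                            df["coefficient"].astype(float))), notes)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "cell_type": list(self.coefficients),
            "coefficient": list(self.coefficients.values()),
            "provenance": [self.provenance.get(ct, "")
                           for ct in self.coefficients],
        }).to_csv(path, sep="\t", index=False)


def default_calibration() -> CalibrationTable:
    """Published divisor for neutrophils; identity elsewhere."""
    return CalibrationTable(
        coefficients={"neutrophil": NEUTROPHIL_DIVISOR},
        provenance={"neutrophil": "published spike-in calibration"},
    )


@dataclass
class CellTypeQuant:
    sample_id: str
    cell_type: str
    raw_fraction: float | None
    corrected_fraction: float | None
    ge_per_ml: float | None
    n_markers_used: int
    flags: tuple[str, ...] = ()


def aggregate_cell_type(marker_counts: Sequence[MarkerCount],
                        weighted: bool = False,
                        ) -> tuple[float | None, int, tuple[str, ...]]:
    """Combine one cell type's marker fractions into a raw fraction.

    Returns (raw_fraction or None, n_markers_used, flags). Markers with
    undefined fractions (zero retained reads) are dropped with a flag;
    ``weighted=True`` pools retained-read counts instead of averaging.
    """
    defined = [m for m in marker_counts if m.fraction is not None]
    flags: list[str] = []
    if len(defined) < len(marker_counts):
        flags.append("markers_missing")
    if not defined:
        return None, 0, ("all_markers_undefined",)
    if weighted:
        total = sum(m.n_retained for m in defined)
        frac = sum(m.n_fully_unmethylated for m in defined) / total
    else:
        frac = sum(m.fraction for m in defined) / len(defined)
    return frac, len(defined), tuple(flags)


def apply_calibration(raw_fraction: float, cell_type: str,
                      table: CalibrationTable,
                      ) -> tuple[float, tuple[str, ...]]:
    """corrected = raw / coefficient; values above 1 kept but flagged."""
    coef = table.coefficient(cell_type)
    corrected = raw_fraction / coef
    flags = ("corrected_above_one",) if corrected > 1 else ()
    return corrected, flags


def to_genome_equivalents(corrected_fraction: float,
                          meta: SampleMeta) -> float | None:
    """GE/ml = corrected_fraction x cfDNA conc (ng/ml) x genomes per ng."""
    if meta.cfdna_conc is None:
        return None
    return corrected_fraction * meta.cfdna_conc * GENOMES_PER_NG


def quantify_sample(marker_counts: dict[str, MarkerCount], panel: Panel,
                    meta: SampleMeta,
                    calibration: CalibrationTable | None = None,
                    weighted: bool = False) -> list[CellTypeQuant]:
    """One CellTypeQuant per panel cell type, deterministic.

    Fractions are per-assay and never renormalized across cell types.
    """
    if calibration is None:
        calibration = default_calibration()
    out: list[CellTypeQuant] = []
    for cell_type in panel.cell_types:
        names = panel.cell_type_groups[cell_type]
        mcs = [marker_counts[n] for n in names if n in marker_counts]
        raw, n_used, flags = aggregate_cell_type(mcs, weighted=weighted)
        if raw is None:
            out.append(CellTypeQuant(meta.sample_id, cell_type, None, None,
                                     None, 0, flags))
            continue
        corrected, cal_flags = apply_calibration(raw, cell_type, calibration)
        flags = flags + cal_flags
        ge = to_genome_equivalents(corrected, meta)
        if ge is None:
            flags = flags + ("no_cfdna_conc",)
        out.append(CellTypeQuant(meta.sample_id, cell_type, raw, corrected,
                                 ge, n_used, flags))
    return out


def quants_to_frame(quants: Iterable[CellTypeQuant]):
    import pandas as pd

    return pd.DataFrame([
        {"sample_id": q.sample_id, "cell_type": q.cell_type,
         "raw_fraction": q.raw_fraction,
         "corrected_fraction": q.corrected_fraction,
         "ge_per_ml": q.ge_per_ml, "n_markers_used": q.n_markers_used,
         "flags": ";".join(q.flags)}
        for q in quants
    ])
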