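"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (parameters, seed): methylation
atlases with planted cell-type-specific hypomethylated CpG clusters,
bisulfite amplicon reads drawn from cell-type mixtures (with conversion
failure and sequencing error), and longitudinal cohort tables whose cfDNA
values follow a turnover model (cell number over lifespan) while blood
counts follow per-donor set points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import MethylationAtlas
from .panel import Panel
from .readcall import ReadRecord, revcomp

# ---------------------------------------------------------------------------
# atlas simulation

DEFAULT_CELL_TYPES = ("neutrophil", "monocyte", "eosinophil", "b_cell",
                      "t_cell", "cd8_t_cell", "treg")

#: spacing that keeps every planted CpG's centered 150 bp window >= 6 CpGs
_CLUSTER_SPACING_BP = 15


def simulate_atlas(n_cpgs: int = 1000,
                   cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
                   n_other_tissues: int = 25,
                   planted_per_type: int = 12,
                   seed: int = 0) -> tuple[MethylationAtlas, pd.DataFrame]:
    """Atlas with `planted_per_type` clustered perfect markers per type.

    Background CpGs are methylated everywhere (betas 0.85-1.0) and placed
    1 kb apart; planted CpGs are hypomethylated (< 0.1) in their one cell
    type, clustered tightly enough to pass the density filter. Returns the
    atlas and a truth table (cpg_id, planted_type).
    """
    if planted_per_type < 0:
        raise ValueError("planted_per_type must be >= 0")
    rng = np.random.default_rng(seed)
    columns = list(cell_types) + [f"tissue_{i:02d}"
                                  for i in range(n_other_tissues)]
    n_planted = planted_per_type * len(cell_types)
    if n_planted > n_cpgs:
        raise ValueError("more planted CpGs than n_cpgs")

    # five methylated companion CpGs lead each cluster so that every planted
    # CpG has >= 6 atlas CpGs in its centered 150 bp window even when
    # planted_per_type is small
    n_companions = 5
    total_companions = (n_companions * len(cell_types)
                        if planted_per_type else 0)
    if n_planted + total_companions > n_cpgs:
        raise ValueError("n_cpgs too small for planted clusters")

    ids, chroms, positions, planted_type = [], [], [], []
    pos = 1_000
    k = 0
    for ct in cell_types:
        if planted_per_type == 0:
            continue
        for _ in range(n_companions):
            ids.append(f"cg{k:08d}")
            chroms.append("chr1")
            positions.append(pos)
            planted_type.append("")
            pos += _CLUSTER_SPACING_BP
            k += 1
        for _ in range(planted_per_type):
            ids.append(f"cg{k:08d}")
            chroms.append("chr1")
            positions.append(pos)
            planted_type.append(ct)
            pos += _CLUSTER_SPACING_BP
            k += 1
        pos += 10_000  # gap between clusters
    for _ in range(n_cpgs - n_planted - total_companions):
        ids.append(f"cg{k:08d}")
        chroms.append("chr1")
        positions.append(pos)
        planted_type.append("")
        pos += 1_000
        k += 1

    betas = rng.uniform(0.85, 1.0, size=(n_cpgs, len(columns)))
    for i, ct in enumerate(planted_type):
        if ct:
            betas[i, columns.index(ct)] = rng.uniform(0.0, 0.1)

    atlas = MethylationAtlas(
        betas=pd.DataFrame(betas, index=pd.Index(ids, name="cpg_id"),
                           columns=columns),
        coords=pd.DataFrame({"chrom": chroms, "pos": positions},
                            index=pd.Index(ids, name="cpg_id")))
    truth = pd.DataFrame({"cpg_id": ids, "planted_type": planted_type})
    return atlas, truth


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class ReadSimConfig:
    depth: int = 1000            # reads per marker
    conversion_rate: float = 0.99
    sequencing_error: float = 0.003
    revcomp_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("conversion_rate", "sequencing_error",
                     "revcomp_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i

BACKGROUND = "background"


def _default_pattern(cell_type: str, amplicon) -> np.ndarray:
    """True = methylated. A cell type is unmethylated at its own markers."""
    meth = cell_type != amplicon.cell_type
    return np.full(amplicon.n_cpgs, meth, dtype=bool)


def simulate_reads(panel: Panel, mixture: Mapping[str, float],
                   config: ReadSimConfig = ReadSimConfig(),
                   patterns: Mapping[str, Mapping[str, Sequence[bool]]]
                   | None = None,
                   ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw `depth` reads per marker from a cell-type mixture.

    Each read's source cell type is drawn proportionally to ``mixture``
    (which must sum to 1; the key ``"background"`` denotes immune-null
    DNA, methylated everywhere). Unmethylated CpG cytosines and non-CpG
    cytosines convert to T with probability ``conversion_rate``;
    methylated CpG cytosines stay C. Substitution errors replace a base
    with one of the other three. Returns the reads plus a per-read truth
    table.
    """
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture sums to {total}, expected 1")
    rng = np.random.default_rng(config.seed)
    cell_types = list(mixture)
    probs = np.array([mixture[ct] for ct in cell_types], dtype=float)

    reads: list[ReadRecord] = []
    truth_rows = []
    counter = 0
    for amp in panel:
        ref = np.frombuffer(amp.ref_seq.encode(), dtype=np.uint8)
        length = ref.shape[0]
        cpg_cols = np.array(amp.cpg_offsets, dtype=int)
        qc_cols = np.array(amp.non_cpg_c_offsets, dtype=int)
        sources = rng.choice(len(cell_types), size=config.depth, p=probs)
        for ci, ct in enumerate(cell_types):
            n = int(np.sum(sources == ci))
            if n == 0:
                continue
            if patterns and ct in patterns and amp.name in patterns[ct]:
                meth = np.asarray(patterns[ct][amp.name], dtype=bool)
            elif ct == BACKGROUND:
                meth = np.ones(amp.n_cpgs, dtype=bool)
            else:
                meth = _default_pattern(ct, amp)
            mat = np.tile(ref, (n, 1))
            # bisulfite conversion of unmethylated CpG Cs and non-CpG Cs
            unmeth_cols = cpg_cols[~meth]
            conv_cols = np.concatenate([unmeth_cols, qc_cols])
            if conv_cols.size:
                hit = rng.random((n, conv_cols.size)) < config.conversion_rate
                sub = mat[:, conv_cols]
                sub[hit] = ord("T")
                mat[:, conv_cols] = sub
            # substitution errors to one of the other three bases
            err = rng.random((n, length)) < config.sequencing_error
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()))
                idx = _BASE_IDX[mat[err]]
                mat[err] = _BASES[(idx + shift) % 4]
            flip = rng.random(n) < config.revcomp_fraction
            blob = mat.tobytes().decode("ascii")
            const_quals = (37,) * length
            err_rows = set(np.nonzero(err.any(axis=1))[0].tolist())
            for r in range(n):
                seq = blob[r * length:(r + 1) * length]
                if r in err_rows:
                    q = tuple(20 if e else 37 for e in err[r])
                else:
                    q = const_quals
                if flip[r]:
                    seq = revcomp(seq)
                    q = q[::-1]
                rid = f"r{counter:08d}"
                counter += 1
                reads.append(ReadRecord(rid, seq, q))
                truth_rows.append({
                    "read_id": rid, "marker": amp.name, "source": ct,
                    "pattern_fully_unmethylated": bool(~meth.any()),
                    "orientation": "-" if flip[r] else "+"})
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return reads, truth


def theoretical_unmeth_call_rate(panel: Panel, cell_type: str,
                                 config: ReadSimConfig) -> float:
    """Expected fully-unmethylated call rate for a read of `cell_type` at
    its own markers, under the generative model.

    Each unmethylated CpG reads TG iff its C converted (probability
    ``conversion_rate``) and neither base of the dinucleotide was hit by a
    substitution error; a marker needs all its CpGs to read TG. Averaged
    over the cell type's markers, this is the slope a perfect recovery fit
    should find against the designed mixture fractions.
    """
    p_cpg = config.conversion_rate * (1 - config.sequencing_error) ** 2
    rates = [p_cpg ** amp.n_cpgs for amp in panel
             if amp.cell_type == cell_type]
    if not rates:
        raise ValueError(f"no markers for cell type {cell_type!r}")
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# cohort simulation

#: healthy baseline GE/ml means per cell type (generator parameters)
BASELINE_GE: dict[str, float] = {
    "neutrophil": 390.0, "monocyte": 101.0, "eosinophil": 38.0,
    "t_cell": 30.0, "b_cell": 17.0, "cd8_t_cell": 8.0, "treg": 2.0,
}

#: typical blood counts, cells/ul
COUNT_MEAN: dict[str, float] = {
    "neutrophil": 4000.0, "monocyte": 500.0, "eosinophil": 200.0,
    "t_cell": 1200.0, "b_cell": 300.0, "cd8_t_cell": 500.0, "treg": 60.0,
}

VACCINATION_TIMEPOINTS = ("D0", "D3", "D7", "D28")
HEALTHY_TIMEPOINTS = ("W1", "W2", "W3", "W4", "W5", "W6")

STRAINS = ("H1N1", "H3", "YAMA", "VIC")


@dataclass(frozen=True)
class CohortScenario:
    """Parameters of a simulated cohort.

    cfDNA release follows turnover (cell number / lifespan): lifespans are
    implied by ``count_mean / baseline_ge`` so that population-mean
    turnover equals the configured baseline GE/ml. Counts get per-donor
    lognormal set points (low within-donor noise); cfDNA gets shared
    population noise with no donor set point.
    """

    name: str = "healthy"
    baseline_ge: Mapping[str, float] = field(
        default_factory=lambda: dict(BASELINE_GE))
    count_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(COUNT_MEAN))
    cfdna_sigma: float = 0.5
    count_setpoint_sigma: float = 0.35
    count_within_sigma: float = 0.08
    # vaccination
    responder_fraction: float = 0.8
    responder_cfdna_fold: Mapping[str, float] = field(
        default_factory=lambda: {"D0": 1.0, "D3": 3.0, "D7": 5.0,
                                 "D28": 1.2})
    nonresponder_cfdna_fold: Mapping[str, float] = field(
        default_factory=lambda: {"D0": 1.0, "D3": 1.2, "D7": 1.4,
                                 "D28": 1.0})
    bcell_count_fold: Mapping[str, float] = field(
        default_factory=lambda: {"D0": 1.0, "D3": 1.0, "D7": 1.3,
                                 "D28": 1.2})
    # EoE: eosinophil cfDNA group means, GE/ml
    eoe_group_means: Mapping[str, float] = field(
        default_factory=lambda: {"active": 115.0, "remission": 36.0,
                                 "control": 34.0})
    # lymphoma
    lymphoma_bcell_cfdna_fold: float = 20.0
    lymphoma_bcell_count_fold: float = 0.5


@dataclass
class CohortData:
    measurements: pd.DataFrame
    truth: pd.DataFrame
    titers: pd.DataFrame | None = None


def _lognormal(rng: np.random.Generator, sigma: float, size=None):
    """Mean-preserving multiplicative lognormal noise."""
    return np.exp(rng.normal(0.0, sigma, size=size) - sigma**2 / 2)


def simulate_cohort(scenario: CohortScenario | str = "healthy",
                    n_donors: int = 15,
                    timepoints: Sequence[str] | None = None,
                    seed: int = 0) -> CohortData:
    """Generate longitudinal cfDNA + CBC tables for one scenario.

    Scenarios: ``healthy`` (no effects), ``vaccination`` (B-cell cfDNA
    fold rise peaking at day 7 with day-3 counts unchanged, plus an HI
    titer table), ``eoe`` (eosinophil cfDNA elevated in the active group,
    counts unchanged), ``lymphoma`` (B-cell cfDNA up, B-cell counts
    down).
    """
    if isinstance(scenario, str):
        scenario = CohortScenario(name=scenario)
    rng = np.random.default_rng(seed)
    name = scenario.name
    if timepoints is None:
        timepoints = (VACCINATION_TIMEPOINTS if name == "vaccination"
                      else HEALTHY_TIMEPOINTS if name == "healthy"
                      else ("T0",))
    cell_types = list(scenario.baseline_ge)
    donors = [f"donor_{i:02d}" for i in range(n_donors)]

    # donor-level latent state
    if name == "vaccination":
        responder = rng.random(n_donors) < scenario.responder_fraction
        groups = ["vaccinated"] * n_donors
    else:
        responder = np.full(n_donors, None)
        groups = ["healthy"] * n_donors
    if name == "eoe":
        pool = ["active", "remission", "control"]
        groups = [pool[i % 3] for i in range(n_donors)]
    elif name == "lymphoma":
        groups = ["lymphoma" if i % 2 == 0 else "control"
                  for i in range(n_donors)]

    setpoints = {
        (d, ct): scenario.count_mean[ct]
        * float(_lognormal(rng, scenario.count_setpoint_sigma))
        for d in donors for ct in cell_types
    }

    rows = []
    for di, donor in enumerate(donors):
        group = groups[di]
        for tp in timepoints:
            for ct in cell_types:
                count_fold = 1.0
                cfdna_fold = 1.0
                cfdna_mean = scenario.baseline_ge[ct]
                if name == "vaccination" and ct == "b_cell":
                    fold_map = (scenario.responder_cfdna_fold if responder[di]
                                else scenario.nonresponder_cfdna_fold)
                    cfdna_fold = fold_map[tp]
                    count_fold = scenario.bcell_count_fold[tp]
                elif name == "eoe" and ct == "eosinophil":
                    cfdna_mean = scenario.eoe_group_means[group]
                elif name == "lymphoma" and ct == "b_cell":
                    if group == "lymphoma":
                        cfdna_fold = scenario.lymphoma_bcell_cfdna_fold
                        count_fold = scenario.lymphoma_bcell_count_fold
                # turnover: population cell number / lifespan, shared
                # population noise (no donor set point for cfDNA)
                lifespan = scenario.count_mean[ct] / scenario.baseline_ge[ct]
                turnover = (scenario.count_mean[ct] / lifespan) \
                    * cfdna_mean / scenario.baseline_ge[ct]
                cfdna = turnover * cfdna_fold \
                    * float(_lognormal(rng, scenario.cfdna_sigma))
                count = setpoints[(donor, ct)] * count_fold \
                    * float(_lognormal(rng, scenario.count_within_sigma))
                rows.append({"donor_id": donor, "timepoint": tp,
                             "source": "cfDNA", "analyte": ct,
                             "value": cfdna, "units": "GE/ml",
                             "group": group})
                rows.append({"donor_id": donor, "timepoint": tp,
                             "source": "CBC", "analyte": ct,
                             "value": count, "units": "cells/ul",
                             "group": group})

    measurements = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "donor_id": donors, "group": groups,
        "responder": list(responder),
    })

    titers = None
    if name == "vaccination":
        titer_rows = []
        for di, donor in enumerate(donors):
            base = [20] * len(STRAINS)
            for si in range(1, len(STRAINS)):
                if rng.random() < 0.3:
                    base[si] = int(rng.choice([80, 160]))
            post = list(base)
            if responder[di]:
                post[0] = int(rng.choice([80, 160, 320, 640]))
            for si, strain in enumerate(STRAINS):
                titer_rows.append({
                    "donor_id": donor, "strain": strain,
                    "baseline_titer": base[si], "post_titer": post[si]})
        titers = pd.DataFrame(titer_rows)

    return CohortData(measurements=measurements, truth=truth, titers=titers)
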