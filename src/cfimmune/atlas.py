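"""Discovery of cell-type-specific hypomethylated CpG markers.

A reference methylation atlas (rows = CpG sites, columns = tissues and
sorted cell types, values = beta methylation fractions) is scanned for
CpGs that are hypomethylated in one target cell type while methylated in
the large majority of other columns, locally CpG-dense, and top-ranked by
beta separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerCriteria:
    """Thresholds for candidate CpG selection.

    Parameters
    ----------
    beta_target_max : float
        Mean beta in the target cell type must be strictly below this.
    beta_other_min : float
        A non-target column counts as methylated if its beta is strictly
        above this.
    other_pass_fraction : float
        Strictly more than this fraction of non-target columns must be
        methylated.
    window_bp : int
        Width of the genomic window centered on the candidate used for the
        CpG density filter.
    min_cpgs_in_window : int
        Minimum number of atlas CpGs (candidate included) in the window.
    top_k : int
        Number of top-ranked candidates retained per cell type.
    max_missing_fraction : float
        CpGs with more than this fraction of missing betas are excluded.
    """

    beta_target_max: float = 0.3
    beta_other_min: float = 0.8
    other_pass_fraction: float = 0.90
    window_bp: int = 150
    min_cpgs_in_window: int = 6
    top_k: int = 10
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.beta_target_max < self.beta_other_min <= 1):
            raise ValueError(
                "require 0 <= beta_target_max < beta_other_min <= 1, got "
                f"{self.beta_target_max} / {self.beta_other_min}"
            )
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_cpgs_in_window < 1:
            raise ValueError("min_cpgs_in_window must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class CandidateCpG:
    """A CpG passing the specificity predicates, with its statistics."""

    cpg_id: str
    target_cell_type: str
    chrom: str
    pos: int
    beta_target: float
    mean_other: float
    fraction_other_above: float
    margin: float
    n_cpgs_in_window: int | None = None


@dataclass
class MethylationAtlas:
    """Beta-value matrix with CpG coordinates and column group labels.

    Attributes
    ----------
    betas : pandas.DataFrame
        Index = cpg_id, columns = sample labels, values in [0, 1] or NaN.
    coords : pandas.DataFrame
        Index = cpg_id, columns ``chrom`` and ``pos`` (1-based,
        array-probe convention). Sorted by (chrom, pos).
    groups : dict
        Sample label -> cell-type/tissue group. Defaults to identity.
    """

    betas: pd.DataFrame
    coords: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.betas.shape[1] < 2:
            raise ValueError("atlas needs at least 2 columns")
        if self.betas.index.has_duplicates:
            dups = self.betas.index[self.betas.index.duplicated()].unique()
            raise ValueError(f"duplicate cpg_id(s): {list(dups)[:5]}")
        vals = self.betas.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            row = self.betas.index[np.where(bad & ~np.isnan(vals))[0][0]]
            raise ValueError(f"beta outside [0, 1] at CpG {row!r}")
        if not self.groups:
            self.groups = {c: c for c in self.betas.columns}
        order = self.coords.sort_values(["chrom", "pos"]).index
        self.coords = self.coords.loc[order]
        self.betas = self.betas.loc[order]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def column_labels(self) -> list[str]:
        return list(self.betas.columns)

    def columns_for(self, group: str) -> list[str]:
        cols = [c for c in self.betas.columns if self.groups.get(c) == group]
        if not cols:
            raise KeyError(f"unknown target label: {group!r}")
        return cols


def load_atlas(path: str | Path, sep: str = "\t",
               groups: Mapping[str, str] | None = None) -> MethylationAtlas:
    """Read an atlas table (cpg_id, chrom, pos, one column per sample)."""
    df = pd.read_csv(path, sep=sep)
    required = {"cpg_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"atlas table must have columns {sorted(required)}")
    df = df.set_index("cpg_id")
    coords = df[["chrom", "pos"]].copy()
    coords["pos"] = coords["pos"].astype(int)
    betas = df.drop(columns=["chrom", "pos"]).astype(float)
    return MethylationAtlas(betas=betas, coords=coords,
                            groups=dict(groups) if groups else {})


def write_markers(candidates: Iterable[CandidateCpG], path: str | Path) -> None:
    pd.DataFrame([c.__dict__ for c in candidates]).to_csv(
        path, sep="\t", index=False)


def find_candidate_cpgs(atlas: MethylationAtlas, target: str,
                        criteria: MarkerCriteria = MarkerCriteria(),
                        ) -> list[CandidateCpG]:
    """CpGs hypomethylated in `target` and methylated in most other columns.

    A CpG qualifies when its mean beta over the target columns is strictly
    below ``beta_target_max`` and strictly more than ``other_pass_fraction``
    of the non-target columns (with non-missing betas) exceed
    ``beta_other_min``.
    """
    target_cols = atlas.columns_for(target)
    other_cols = [c for c in atlas.betas.columns if c not in target_cols]
    if not other_cols:
        raise ValueError("atlas has no non-target columns")

    tmat = atlas.betas[target_cols].to_numpy(dtype=float)
    omat = atlas.betas[other_cols].to_numpy(dtype=float)
    n_cols = atlas.betas.shape[1]

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        beta_target = np.nanmean(tmat, axis=1)
        mean_other = np.nanmean(omat, axis=1)
    n_other_defined = np.sum(~np.isnan(omat), axis=1)
    n_above = np.sum(omat > criteria.beta_other_min, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_above = np.where(n_other_defined > 0,
                              n_above / np.maximum(n_other_defined, 1), np.nan)

    n_missing = (np.sum(np.isnan(tmat), axis=1)
                 + np.sum(np.isnan(omat), axis=1))
    out: list[CandidateCpG] = []
    for i, cpg_id in enumerate(atlas.cpg_ids):
        if n_missing[i] == n_cols:
            logger.info("CpG %s: all values missing, skipped", cpg_id)
            continue
        if n_missing[i] / n_cols > criteria.max_missing_fraction:
            logger.info("CpG %s: >%d%% missing, excluded", cpg_id,
                        int(criteria.max_missing_fraction * 100))
            continue
        if np.isnan(beta_target[i]) or n_other_defined[i] == 0:
            continue
        if not (beta_target[i] < criteria.beta_target_max
                and frac_above[i] > criteria.other_pass_fraction):
            continue
        out.append(CandidateCpG(
            cpg_id=str(cpg_id),
            target_cell_type=target,
            chrom=str(atlas.coords.at[cpg_id, "chrom"]),
            pos=int(atlas.coords.at[cpg_id, "pos"]),
            beta_target=float(beta_target[i]),
            mean_other=float(mean_other[i]),
            fraction_other_above=float(frac_above[i]),
            margin=float(mean_other[i] - beta_target[i]),
        ))
    return out


def density_filter(candidates: Sequence[CandidateCpG],
                   atlas: MethylationAtlas,
                   criteria: MarkerCriteria = MarkerCriteria(),
                   ) -> list[CandidateCpG]:
    """Keep candidates whose centered window holds enough atlas CpGs.

    The window of ``window_bp`` is centered on the candidate position and
    the count includes the candidate itself.
    """
    half = criteria.window_bp / 2
    by_chrom: dict[str, np.ndarray] = {
        str(ch): np.sort(sub["pos"].to_numpy())
        for ch, sub in atlas.coords.groupby("chrom")
    }
    known = set(map(str, atlas.cpg_ids))
    kept: list[CandidateCpG] = []
    for cand in candidates:
        if cand.cpg_id not in known:
            raise KeyError(f"candidate {cand.cpg_id} absent from atlas")
        positions = by_chrom[cand.chrom]
        lo = np.searchsorted(positions, cand.pos - half, side="left")
        hi = np.searchsorted(positions, cand.pos + half, side="right")
        n_in = int(hi - lo)
        if n_in >= criteria.min_cpgs_in_window:
            kept.append(CandidateCpG(**{**cand.__dict__,
                                        "n_cpgs_in_window": n_in}))
    return kept


def select_top_k(candidates: Sequence[CandidateCpG],
                 criteria: MarkerCriteria = MarkerCriteria(),
                 ) -> dict[str, list[CandidateCpG]]:
    """Rank candidates per cell type and keep the top ``top_k``.

    Ranking: margin (mean non-target beta minus target beta) descending,
    ties broken by fraction_other_above descending then by genomic
    coordinate, so output is deterministic.
    """
    by_type: dict[str, list[CandidateCpG]] = {}
    for c in candidates:
        by_type.setdefault(c.target_cell_type, []).append(c)
    selected: dict[str, list[CandidateCpG]] = {}
    for cell_type, cands in sorted(by_type.items()):
        ranked = sorted(cands, key=lambda c: (-c.margin,
                                              -c.fraction_other_above,
                                              c.chrom, c.pos))
        if len(ranked) < criteria.top_k:
            logger.warning("%s: only %d candidates (< top_k=%d)",
                           cell_type, len(ranked), criteria.top_k)
        selected[cell_type] = ranked[:criteria.top_k]
    return selected


def discover_markers(atlas: MethylationAtlas, targets: Iterable[str],
                     criteria: MarkerCriteria = MarkerCriteria(),
                     ) -> dict[str, list[CandidateCpG]]:
    """Full pipeline: candidate scan, density filter, top-k ranking."""
    pool: list[CandidateCpG] = []
    for target in targets:
        cands = find_candidate_cpgs(atlas, target, criteria)
        pool.extend(density_filter(cands, atlas, criteria))
    return select_top_k(pool, criteria)
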