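"""Quantitative-quality and validation metrics.

Covers the checks used to establish that a micro-scaffold mapping run is
trustworthy: replicate precision of the pooled QC sample (per-protein CV% on
the linear scale and pairwise log2 Pearson r between QC runs), linearity of
cumulative recovered protein amount versus cumulative specimen count, and
recovery of a designed spike-in pattern (non-endogenous peptides placed at
known fold levels across wells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gridio import MISSING_TOKEN, QCSet, SpatialGrid, Well, _sniff_delimiter
from .mapping import ProteinMap

#: the five designed spike-in fold levels
SPIKE_LEVELS = (0.5, 0.7, 1.0, 1.3, 2.0)
#: default non-endogenous spike-in peptide sequences
SPIKE_PEPTIDES = ("GPSVFPLAPSSK", "LLINVGSR", "LLIIGASTR")


@dataclass
class QCReport:
    per_protein_cv: dict[str, float]  # CV% on the linear scale
    median_cv: float
    replicate_r: pd.DataFrame  # pairwise pearson r between QC runs (log2)
    n_replicates: int

    @property
    def replicate_r_median(self) -> float:
        """Median off-diagonal pairwise r."""
        r = self.replicate_r.to_numpy()
        iu = np.triu_indices_from(r, k=1)
        return float(np.nanmedian(r[iu]))

    @property
    def replicate_r_range(self) -> tuple[float, float]:
        r = self.replicate_r.to_numpy()
        iu = np.triu_indices_from(r, k=1)
        return float(np.nanmin(r[iu])), float(np.nanmax(r[iu]))


def qc_cv(qc: QCSet) -> QCReport:
    """Replicate precision of the pooled QC sample.

    CV% per protein is computed on linear-scale abundances (2**log2) over the
    QC runs where the protein was observed (requires ≥2 observations; sample
    sd, divisor n−1).  Pairwise Pearson r between runs is computed on the
    log2 values, pairwise-complete.
    """
    if qc.n_runs < 2:
        raise ValueError(f"need at least 2 QC runs, got {qc.n_runs}")
    log2_vals = qc.quant.values  # runs x proteins
    linear = np.power(2.0, log2_vals)
    mean = linear.mean(axis=0, skipna=True)
    sd = linear.std(axis=0, ddof=1, skipna=True)
    n_obs = linear.notna().sum(axis=0)
    ok = (n_obs >= 2) & (mean > 0)
    cv = (100.0 * sd / mean)[ok]
    rep_r = log2_vals.T.corr(method="pearson", min_periods=3)
    return QCReport(
        per_protein_cv=cv.to_dict(),
        median_cv=float(cv.median()),
        replicate_r=rep_r,
        n_replicates=qc.n_runs,
    )


def cumulative_linearity(
    amounts: Sequence[float], order: Sequence[int] | None = None
) -> float:
    """R² of cumulative protein amount against cumulative specimen count.

    A near-1 R² indicates uniform recovery across micro-specimens — the
    compartmentalization/preparation reproducibility check.
    """
    a = np.asarray(amounts, dtype=float)
    if order is not None:
        a = a[np.asarray(order, dtype=int)]
    if len(a) < 3:
        raise ValueError("need at least 3 specimens")
    if np.any(a < 0):
        raise ValueError("amounts must be non-negative")
    if np.all(a == 0):
        raise ValueError("all amounts are zero")
    y = np.cumsum(a)
    x = np.arange(1, len(a) + 1, dtype=float)
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


@dataclass
class SpikeDesign:
    """Location → theoretical fold level for the spiked non-endogenous peptides."""

    peptide_ids: list[str] = field(default_factory=lambda: list(SPIKE_PEPTIDES))
    level_of_well: dict[Well, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, lvl in self.level_of_well.items():
            if lvl <= 0:
                raise ValueError(f"fold level at {w} must be positive, got {lvl}")

    def to_map(self, grid: SpatialGrid) -> ProteinMap:
        """The theoretical spike map: designed fold level, missing off-design."""
        for w in self.level_of_well:
            if w not in grid.wells:
                raise ValueError(f"designed well {w} is not occupied on the grid")
        cells = {
            w: float(self.level_of_well.get(w, np.nan)) for w in grid.wells
        }
        return ProteinMap(
            grid=grid, protein_id="+".join(self.peptide_ids), cell_values=cells,
            scale_tag="linear",
        )


def read_spike_design(path: str | Path) -> SpikeDesign:
    """Read a design table with columns ``row, col, level`` (and optional
    ``# peptides=A,B,C`` header line)."""
    path = Path(path)
    peptides = list(SPIKE_PEPTIDES)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "peptides=" in line:
                peptides = line.split("peptides=", 1)[1].strip().split(",")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    levels = {(int(r.row), int(r.col)): float(r.level) for r in df.itertuples()}
    return SpikeDesign(peptide_ids=peptides, level_of_well=levels)


def write_spike_design(design: SpikeDesign, path: str | Path) -> None:
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, "w") as fh:
        fh.write(f"# peptides={','.join(design.peptide_ids)}\n")
        fh.write(sep.join(["row", "col", "level"]) + "\n")
        for (r, c), lvl in sorted(design.level_of_well.items()):
            fh.write(sep.join([str(r), str(c), "%g" % lvl]) + "\n")


def spike_error(
    theoretical: ProteinMap,
    measured: ProteinMap,
    measured_is_log2: bool = False,
    anchor: str = "one_fold",
) -> tuple[float, pd.DataFrame]:
    """Mean percent error between a measured spike map and its design.

    With ``anchor='one_fold'`` (default) the measured map is first rescaled
    so the mean over the 1-fold wells matches the theoretical 1-fold level
    (ratio-scale anchoring; falls back to the overall measured/theoretical
    mean ratio if the design has no 1-fold wells).  ``anchor='none'``
    compares the raw values, assuming the measurement is already on the
    design's absolute scale.  The error at each well where both maps are
    defined is ``100 · |measured − theoretical| / theoretical`` (linear scale).
    """
    if theoretical.grid.wells != measured.grid.wells:
        raise ValueError("maps must share one grid")
    t = theoretical.values_vector()
    m = measured.values_vector()
    if measured_is_log2:
        m = np.power(2.0, m)
    both = ~np.isnan(t) & ~np.isnan(m)
    if not both.any():
        raise ValueError("no overlapping spiked wells between design and measurement")
    if np.any(t[both] <= 0):
        raise ValueError("theoretical levels must be positive on spiked wells")
    if anchor == "one_fold":
        anchor_mask = both & np.isclose(t, 1.0)
        if anchor_mask.any():
            scale = float(np.mean(m[anchor_mask]))  # -> 1-fold wells average to 1
        else:
            scale = float(np.mean(m[both]) / np.mean(t[both]))
    elif anchor == "none":
        scale = 1.0
    else:
        raise ValueError(f"unknown anchor mode {anchor!r}")
    if scale <= 0:
        raise ValueError("cannot anchor: non-positive measured mean")
    m_scaled = m / scale
    err = 100.0 * np.abs(m_scaled[both] - t[both]) / t[both]
    wells = np.array(theoretical.grid.sorted_wells(), dtype=int)[both]
    table = pd.DataFrame(
        {
            "row": wells[:, 0],
            "col": wells[:, 1],
            "theoretical": t[both],
            "measured_scaled": m_scaled[both],
            "error_pct": err,
        }
    )
    return float(err.mean()), table


def spike_rank_recovery(design: SpikeDesign, measured: ProteinMap) -> float:
    """Spearman rank correlation between designed fold levels and the
    per-level mean measured values (1.0 = the level ordering is recovered)."""
    t = design.to_map(measured.grid).values_vector()
    m = measured.values_vector()
    both = ~np.isnan(t) & ~np.isnan(m)
    levels = np.unique(t[both])
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct designed levels")
    means = [float(np.mean(m[both & (t == lvl)])) for lvl in levels]
    rho = stats.spearmanr(levels, means).statistic
    return float(rho)
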