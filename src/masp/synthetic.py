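"""Synthetic whole-tissue datasets with the statistical structure the pipeline assumes.

Emulates a micro-scaffold experiment end to end: an elliptical tissue slice
occupying ~208 wells of a 30×30 lattice (400 µm wells), a few thousand
proteins with log2 abundances, a subset of proteins enriched in contiguous
anatomical regions, heterodimer pairs sharing a latent spatial signal,
Gaussian log2 noise (multiplicative on the linear scale, the usual label-free
LC-MS error model), sparse missingness, and pooled-QC runs injected
periodically through the acquisition.

Default parameters mirror the study conditions the pipeline was built for:
208 occupied wells, 2000 proteins at desk scale, regional effects of
1 log2 unit over noise sd 0.3, nine QC runs (one per ~20 specimens) with
~9.4 % replicate CV, and a per-cell missing rate of 4.4e-4 (which makes a
protein's chance of a complete 208-well map about 91 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gridio import QCSet, QuantMatrix, SpatialGrid, Well
from .mapping import ProteinMap
from .qc import SPIKE_LEVELS, SpikeDesign

DEFAULT_N_ROWS = 30
DEFAULT_N_COLS = 30
DEFAULT_RESOLUTION_UM = 400.0
DEFAULT_TARGET_WELLS = 208
DEFAULT_N_PROTEINS = 2000
DEFAULT_N_QC = 9
DEFAULT_EFFECT_LOG2 = 1.0
DEFAULT_NOISE_SD_LOG2 = 0.3
DEFAULT_MISSING_RATE = 4.4e-4
DEFAULT_QC_CV_LINEAR = 0.094
DEFAULT_FRAC_REGIONAL = 0.10
DEFAULT_N_REGIONS = 4
BASELINE_LOG2_RANGE = (18.0, 30.0)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset (what tests recover against)."""

    region_of_well: dict[Well, str]
    effect_of_protein: dict[str, dict[str, float]]  # protein -> region -> log2 offset
    heterodimer_pairs: list[tuple[str, str, float]]  # (a, b, shared fraction)
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2
    missing_rate: float = DEFAULT_MISSING_RATE
    qc_cv_linear: float = DEFAULT_QC_CV_LINEAR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for a, b, s in self.heterodimer_pairs:
            if not 0 <= s <= 1:
                raise ValueError(f"shared fraction for ({a}, {b}) must lie in [0, 1]")

    @property
    def regional_proteins(self) -> list[str]:
        return sorted(self.effect_of_protein)


# ---------------------------------------------------------------------------
# grid generation
# ---------------------------------------------------------------------------


def generate_grid(
    n_rows: int = DEFAULT_N_ROWS,
    n_cols: int = DEFAULT_N_COLS,
    occupancy_shape: str = "ellipse",
    target_wells: int | None = DEFAULT_TARGET_WELLS,
    resolution_um: float = DEFAULT_RESOLUTION_UM,
) -> SpatialGrid:
    """Deterministic occupancy mask shaped like a tissue slice.

    ``occupancy_shape`` is one of ``ellipse`` (a centered slice),
    ``annulus`` (a ring), ``half`` (a half-plane) or ``full``.  When
    ``target_wells`` is given, exactly that many wells are occupied (the
    wells best matching the shape are kept; ties broken row-major).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid dimensions must be >= 2")
    r0, c0 = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    # normalized elliptical radius in [0, ~1.4]
    rad = np.sqrt(((rows - r0) / (n_rows / 2.0)) ** 2 + ((cols - c0) / (n_cols / 2.0)) ** 2)
    if occupancy_shape == "ellipse":
        score = rad
    elif occupancy_shape == "annulus":
        score = np.abs(rad - 0.6)
    elif occupancy_shape == "half":
        score = np.where(rows <= r0, rad, np.inf)
    elif occupancy_shape == "full":
        score = np.zeros_like(rad)
    else:
        raise ValueError(f"unknown occupancy_shape {occupancy_shape!r}")

    order = sorted(
        ((score[r, c], r, c) for r in range(n_rows) for c in range(n_cols)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    if target_wells is None:
        keep = [(r, c) for s, r, c in order if np.isfinite(s) and s <= 1.0]
    else:
        finite = [(r, c) for s, r, c in order if np.isfinite(s)]
        if target_wells < 1 or target_wells > len(finite):
            raise ValueError(f"target_wells={target_wells} not satisfiable on this mask")
        keep = finite[:target_wells]
    if not keep:
        raise ValueError("occupancy mask is empty")
    keep.sort()
    width = len(str(len(keep)))
    wells = {f"S{i + 1:0{width}d}": w for i, w in enumerate(keep)}
    return SpatialGrid(n_rows, n_cols, resolution_um, wells)


def assign_regions(grid: SpatialGrid, n_regions: int = DEFAULT_N_REGIONS) -> dict[Well, str]:
    """Partition the occupied wells into contiguous angular sectors
    (synthetic stand-ins for anatomical regions)."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    wells = grid.sorted_wells()
    r0 = np.mean([w[0] for w in wells])
    c0 = np.mean([w[1] for w in wells])
    out = {}
    for (r, c) in wells:
        theta = np.arctan2(r - r0, c - c0)  # [-pi, pi]
        k = int((theta + np.pi) / (2 * np.pi) * n_regions) % n_regions
        out[(r, c)] = f"R{k + 1}"
    return out


# ---------------------------------------------------------------------------
# truth construction and dataset generation
# ---------------------------------------------------------------------------


def make_brain_slice_truth(
    grid: SpatialGrid,
    n_proteins: int = DEFAULT_N_PROTEINS,
    frac_regional: float = DEFAULT_FRAC_REGIONAL,
    effect_log2: float = DEFAULT_EFFECT_LOG2,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    missing_rate: float = DEFAULT_MISSING_RATE,
    qc_cv_linear: float = DEFAULT_QC_CV_LINEAR,
    n_regions: int = DEFAULT_N_REGIONS,
    n_heterodimers: int = 2,
    shared_fraction: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """The default 'brain-slice' ground truth on a given grid.

    A fraction of proteins is enriched by ``effect_log2`` in exactly one of
    ``n_regions`` contiguous sectors (round-robin, so every sector has
    planted markers), and ``n_heterodimers`` disjoint protein pairs share a
    latent spatial signal scaled by ``shared_fraction``.
    """
    region_of_well = assign_regions(grid, n_regions)
    regions = sorted(set(region_of_well.values()))
    n_regional = int(round(frac_regional * n_proteins))
    width = len(str(n_proteins))
    ids = [f"P{j + 1:0{width}d}" for j in range(n_proteins)]
    effect = {
        ids[j]: {regions[j % len(regions)]: effect_log2} for j in range(n_regional)
    }
    # heterodimer pairs drawn from the non-regional proteins
    pairs = []
    flat = [pid for pid in ids[n_regional:]]
    for h in range(min(n_heterodimers, len(flat) // 2)):
        pairs.append((flat[2 * h], flat[2 * h + 1], shared_fraction))
    return SyntheticTruth(
        region_of_well=region_of_well,
        effect_of_protein=effect,
        heterodimer_pairs=pairs,
        noise_sd_log2=noise_sd_log2,
        missing_rate=missing_rate,
        qc_cv_linear=qc_cv_linear,
        seed=seed,
    )


def generate_dataset(
    truth: SyntheticTruth,
    grid: SpatialGrid,
    n_proteins: int = DEFAULT_N_PROTEINS,
    n_qc: int = DEFAULT_N_QC,
    missing_mode: str = "uniform",
) -> tuple[QuantMatrix, QCSet, SyntheticTruth]:
    """Materialize a dataset from a ground truth: specimen matrix plus QC runs.

    Per cell: log2 value = protein baseline + region offset (if planted)
    + shared latent signal (heterodimer pairs) + N(0, noise_sd_log2); cells
    are then dropped at ``missing_rate`` (uniform, or abundance-weighted with
    ``missing_mode='intensity'`` where low-baseline proteins lose cells
    preferentially).  QC runs are the pooled mean specimen profile with
    multiplicative linear noise of sd ``qc_cv_linear``, interleaved through
    the acquisition order (one QC per ~20 specimens when n_qc allows).
    Identical seed → identical output.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(truth.seed)
    wells = grid.sorted_wells()
    specimens = [grid.specimen_at(w) for w in wells]
    n = len(specimens)
    width = len(str(n_proteins))
    ids = [f"P{j + 1:0{width}d}" for j in range(n_proteins)]

    baseline = rng.uniform(*BASELINE_LOG2_RANGE, size=n_proteins)
    values = np.tile(baseline, (n, 1))

    # regional offsets
    region_idx = np.array([truth.region_of_well[w] for w in wells])
    col_of = {pid: j for j, pid in enumerate(ids)}
    for pid, offsets in truth.effect_of_protein.items():
        if pid not in col_of:
            continue
        j = col_of[pid]
        for region, off in offsets.items():
            values[region_idx == region, j] += off

    # heterodimer shared latent spatial signal
    for a, b, s in truth.heterodimer_pairs:
        if a not in col_of or b not in col_of:
            continue
        latent = rng.standard_normal(n)
        values[:, col_of[a]] += s * latent
        values[:, col_of[b]] += s * latent

    values = values + rng.normal(0.0, truth.noise_sd_log2, size=values.shape)

    if truth.missing_rate > 0:
        if missing_mode == "uniform":
            drop = rng.random(values.shape) < truth.missing_rate
        elif missing_mode == "intensity":
            # low-abundance proteins lose cells preferentially (rate scaled
            # 0..2x by baseline rank, mean = missing_rate)
            rank = np.argsort(np.argsort(baseline)) / max(n_proteins - 1, 1)
            rate = truth.missing_rate * 2.0 * (1.0 - rank)
            drop = rng.random(values.shape) < rate[None, :]
        else:
            raise ValueError(f"unknown missing_mode {missing_mode!r}")
        values = np.where(drop, np.nan, values)

    mat = QuantMatrix(
        pd.DataFrame(values, index=pd.Index(specimens, name="sample_id"),
                     columns=pd.Index(ids, name="feature_id")),
        scale_tag="log2_raw",
    )

    # pooled QC runs: mean specimen profile + multiplicative replicate noise
    pooled = np.nanmean(values, axis=0)
    qc_ids = [f"QC{k + 1}" for k in range(n_qc)]
    eps = rng.normal(0.0, truth.qc_cv_linear, size=(n_qc, n_proteins))
    qc_linear = np.power(2.0, pooled)[None, :] * np.clip(1.0 + eps, 1e-6, None)
    qc_vals = np.log2(qc_linear)
    qc_mat = QuantMatrix(
        pd.DataFrame(qc_vals, index=pd.Index(qc_ids, name="sample_id"),
                     columns=pd.Index(ids, name="feature_id")),
        scale_tag="log2_raw",
    )

    # acquisition order: QC runs evenly interleaved among the specimens
    slots = np.linspace(0, n + n_qc - 1, n_qc).round().astype(int) if n_qc > 0 else []
    run_index = {qid: int(s) for qid, s in zip(qc_ids, slots)}
    spec_slots = [i for i in range(n + n_qc) if i not in set(run_index.values())]
    specimen_run_index = {sid: spec_slots[i] for i, sid in enumerate(specimens)}
    qcset = QCSet(qc_mat, run_index).assign_specimens(specimen_run_index) if n_qc else None

    return mat, qcset, truth


# ---------------------------------------------------------------------------
# spike-in simulation
# ---------------------------------------------------------------------------


def default_spike_design(grid: SpatialGrid, levels: tuple[float, ...] = SPIKE_LEVELS) -> SpikeDesign:
    """Assign the designed fold levels to vertical bands of occupied wells,
    producing a striped pattern across the slice."""
    wells = sorted(grid.sorted_wells(), key=lambda w: (w[1], w[0]))  # by column
    n = len(wells)
    level_of_well = {
        w: levels[min(int(i * len(levels) / n), len(levels) - 1)] for i, w in enumerate(wells)
    }
    return SpikeDesign(level_of_well=level_of_well)


def generate_spike(
    design: SpikeDesign,
    grid: SpatialGrid,
    noise_sd_linear_fraction: float = 0.10,
    seed: int = 0,
) -> ProteinMap:
    """Simulate the measured spike map: level × (1 + N(0, noise)) per designed
    well, on the linear scale.  Reproducible by seed."""
    rng = np.random.default_rng(seed)
    cells: dict[Well, float] = {w: np.nan for w in grid.wells}
    for w in sorted(design.level_of_well):
        lvl = design.level_of_well[w]
        cells[w] = lvl * max(1.0 + rng.normal(0.0, noise_sd_linear_fraction), 1e-9)
    return ProteinMap(
        grid=grid,
        protein_id="+".join(design.peptide_ids),
        cell_values=cells,
        scale_tag="linear",
    )


def generate_specimen_amounts(
    n: int = DEFAULT_TARGET_WELLS, mean_ug: float = 25.0, cv: float = 0.10, seed: int = 0
) -> np.ndarray:
    """Per-specimen recovered protein amounts (µg) with multiplicative noise."""
    rng = np.random.default_rng(seed)
    return mean_ug * np.clip(1.0 + rng.normal(0.0, cv, size=n), 1e-6, None)
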