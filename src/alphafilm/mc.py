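"""Desk-scale Monte Carlo of Am-241 alphas in a film layer stack.

Geometry: a disk source (default 5 mm active diameter, 48 kBq) emits
alphas isotropically; the upward hemisphere enters the stack of layers
lying face-down on the source (optional air gap, the film's active layer,
polyester backing). Transport is straight-line continuous slowing down:
no angular scattering, no energy straggling. For 5.46 MeV alphas over
track lengths of tens of micrometres the lateral displacement from
scattering is far below the 10 um scoring pitch, and the scored quantity
is a thin-slab mean, so the straight-line model is adequate.

Dose is scored in a single voxel slab spanning the active-layer thickness
(lateral pitch 0.01 mm by default), per decay, with history-by-history
statistical uncertainties from per-history first and second moments.
Downward-emitted alphas are absorbed in the source backing and score
nothing but still count as decays in the normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .materials import (
    AIR,
    E_CUT,
    EBT3_ACTIVE,
    EBTXD_ACTIVE,
    HDV2_ACTIVE,
    POLYESTER,
    WATER,
    Material,
    build_range_table,
)

__all__ = [
    "SourceSpec",
    "LayerStack",
    "DoseGrid",
    "DoseRateResult",
    "AM241_THREE_LINES",
    "sample_emission",
    "transport_alpha",
    "run_simulation",
    "roi_mean_dose_rate",
    "line_profiles",
    "percent_difference_vs_water",
    "film_stack",
    "ACTIVE_LAYERS",
]

GY_PER_MEV_PER_G = 1.602176634e-13 / 1e-3  # MeV/g -> Gy

#: principal alpha lines of Am-241 (MeV, intensity), renormalized
AM241_THREE_LINES: tuple[tuple[float, float], ...] = (
    (5.486, 0.852),
    (5.443, 0.131),
    (5.388, 0.017),
)

#: (material, thickness um) of the active layer per film model
ACTIVE_LAYERS: dict[str, tuple[Material, float]] = {
    "EBT3": (EBT3_ACTIVE, 14.0),
    "EBT-XD": (EBTXD_ACTIVE, 12.0),
    "HD-V2": (HDV2_ACTIVE, 12.0),
}

_BACKING_UM = {"EBT3": 125.0, "EBT-XD": 125.0, "HD-V2": 97.0}


@dataclass(frozen=True)
class SourceSpec:
    """Am-241 disk source.

    activity_bq : decays per second (default 48 kBq).
    active_diameter_mm : diameter of the uniformly active circle.
    spectrum : (energy MeV, intensity) lines; default monoenergetic 5.46 MeV,
        the mean alpha energy of the decay.
    """

    activity_bq: float = 48_000.0
    active_diameter_mm: float = 5.0
    spectrum: tuple[tuple[float, float], ...] = ((5.46, 1.0),)

    def __post_init__(self) -> None:
        if self.activity_bq <= 0:
            raise ValueError("activity must be > 0")
        if self.active_diameter_mm <= 0:
            raise ValueError("active diameter must be > 0")
        total = sum(w for _, w in self.spectrum)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"spectrum intensities sum to {total}, expected 1")


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers (source side first). Exactly one layer is the scored
    active layer; layers before it only degrade the alpha energy."""

    layers: tuple[tuple[Material, float], ...]  # (material, thickness um)
    active_index: int
    label: str = "film"

    def __post_init__(self) -> None:
        if not 0 <= self.active_index < len(self.layers):
            raise ValueError("active_index outside stack")
        for i, (_, t) in enumerate(self.layers):
            if t < 0 or (t == 0 and i != 0):
                raise ValueError("layer thicknesses must be > 0 (gap may be 0)")

    @property
    def active(self) -> tuple[Material, float]:
        return self.layers[self.active_index]

    def water_variant(self) -> "LayerStack":
        """Identical geometry with every layer's material replaced by water."""
        layers = tuple((WATER, t) for _, t in self.layers)
        return LayerStack(layers=layers, active_index=self.active_index, label="water")


def film_stack(model: str, air_gap_um: float = 0.0) -> LayerStack:
    """Build the default stack for a film model: [air gap,] active layer, backing."""
    try:
        active, t_active = ACTIVE_LAYERS[model]
    except KeyError as exc:
        raise KeyError(f"unknown film model {model!r}; choose from {sorted(ACTIVE_LAYERS)}") from exc
    layers: list[tuple[Material, float]] = []
    if air_gap_um > 0:
        layers.append((AIR, air_gap_um))
    layers.append((active, t_active))
    layers.append((POLYESTER, _BACKING_UM[model]))
    return LayerStack(layers=tuple(layers), active_index=len(layers) - 2, label=model)


@dataclass
class DoseGrid:
    """Voxelized energy deposition in the active-layer slab.

    ``esum``/``esumsq`` are per-voxel sums of per-history deposits (MeV) and
    their squares over ``n_histories`` decays; dose and uncertainties derive
    from them.
    """

    pitch_mm: float
    thickness_um: float
    material: Material
    esum: np.ndarray  # (ny, nx) MeV
    esumsq: np.ndarray  # (ny, nx) MeV^2
    n_histories: int
    seed: int
    medium: str = "film"

    @property
    def nx(self) -> int:
        return self.esum.shape[1]

    @property
    def ny(self) -> int:
        return self.esum.shape[0]

    @property
    def voxel_mass_g(self) -> float:
        pitch_cm = self.pitch_mm * 0.1
        return self.material.density * pitch_cm * pitch_cm * (self.thickness_um * 1e-4)

    @property
    def dose_per_decay(self) -> np.ndarray:
        """Gy per decay, per voxel."""
        return self.esum * GY_PER_MEV_PER_G / (self.voxel_mass_g * self.n_histories)

    @property
    def rel_uncertainty(self) -> np.ndarray:
        """History-by-history relative statistical uncertainty of each voxel
        mean (0 where nothing was scored)."""
        n = self.n_histories
        mean = self.esum / n
        var_mean = np.maximum(self.esumsq / n - mean**2, 0.0) / max(n - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mean > 0, np.sqrt(var_mean) / np.where(mean > 0, mean, 1.0), 0.0)
        return rel

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center coordinates (x, y) in mm, origin on the source axis."""
        x = (np.arange(self.nx) - self.nx / 2 + 0.5) * self.pitch_mm
        y = (np.arange(self.ny) - self.ny / 2 + 0.5) * self.pitch_mm
        return x, y

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("dose_Gy_per_decay", data=self.dose_per_decay, compression="gzip")
            f.create_dataset("rel_uncertainty", data=self.rel_uncertainty, compression="gzip")
            x, y = self.coords_mm()
            f.create_dataset("x_mm", data=x)
            f.create_dataset("y_mm", data=y)
            f.attrs.update(
                {
                    "pitch_mm": self.pitch_mm,
                    "thickness_um": self.thickness_um,
                    "material": self.material.name,
                    "density_g_cm3": self.material.density,
                    "n_histories": self.n_histories,
                    "seed": self.seed,
                    "medium": self.medium,
                }
            )


@dataclass(frozen=True)
class DoseRateResult:
    """Mean dose rate in a central circular ROI, normalized to the source
    activity."""

    dose_rate_gy_min: float
    sigma_gy_min: float
    roi_diameter_mm: float
    medium: str
    n_histories: int

    @property
    def sigma_rel_pct(self) -> float:
        return 100.0 * self.sigma_gy_min / self.dose_rate_gy_min


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_emission(
    rng: np.random.Generator, source: SourceSpec, n: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample emission points, upward-hemisphere directions, and energies.

    Returns (positions (n,2) mm, directions (n,3) unit vectors with positive
    z toward the film, energies (n,) MeV). Positions are uniform on the
    active disk; directions isotropic over the upward hemisphere.
    """
    R = source.active_diameter_mm / 2.0
    r = R * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    mu = rng.random(n)  # cos(theta) uniform on (0,1]: isotropic per solid angle
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - mu * mu)
    dirs = np.column_stack([s * np.cos(psi), s * np.sin(psi), mu])
    energies_grid = np.array([e for e, _ in source.spectrum])
    weights = np.array([w for _, w in source.spectrum])
    E = energies_grid[rng.choice(len(energies_grid), size=n, p=weights / weights.sum())]
    return pos, dirs, E


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _transport_kernel(
    x0_um,
    y0_um,
    sx,
    sy,
    mu,
    E0,
    pre_thick_um,  # (n_pre,) thicknesses of layers before the active one
    pre_E,  # (n_pre, m) energy grids of their range tables
    pre_r,  # (n_pre, m) residual ranges (um)
    t_um,  # active-layer thickness
    lay_E,
    lay_r,
    nx,
    ny,
    pitch_um,
    e_cut,
    step_um,
    esum,
    esumsq,
    hist_edep,
):
    n = x0_um.shape[0]
    n_pre = pre_thick_um.shape[0]
    half_x = nx * pitch_um / 2.0
    half_y = ny * pitch_um / 2.0
    for i in range(n):
        m = mu[i]
        if m <= 0.0:
            continue  # absorbed in the source backing
        x = x0_um[i]
        y = y0_um[i]
        E = E0[i]
        alive = True
        # degrade through layers between source and active layer
        for j in range(n_pre):
            path = pre_thick_um[j] / m
            r0 = np.interp(E, pre_E[j], pre_r[j])
            if path >= r0:
                alive = False
                break
            E = np.interp(r0 - path, pre_r[j], pre_E[j])
            x += pre_thick_um[j] * sx[i] / m
            y += pre_thick_um[j] * sy[i] / m
            if E <= e_cut:
                alive = False
                break
        if not alive:
            continue
        # active layer: straight track, residual-range bookkeeping
        total = 0.0
        prev_idx = -2  # -2: nothing buffered; -1: outside grid
        acc = 0.0
        if E <= e_cut:
            # local deposition of sub-cutoff particles in the entry voxel
            ix = int(math.floor((x + half_x) / pitch_um))
            iy = int(math.floor((y + half_y) / pitch_um))
            total = E
            if 0 <= ix < nx and 0 <= iy < ny:
                esum[iy, ix] += E
                esumsq[iy, ix] += E * E
            hist_edep[i] = total
            continue
        r = np.interp(E, lay_E, lay_r)
        s_end = t_um / m
        s_stop = r if r < s_end else s_end
        s = 0.0
        while s < s_stop - 1e-12:
            ds = step_um
            if s + ds > s_stop:
                ds = s_stop - s
            smid = s + 0.5 * ds
            xm = x + smid * sx[i]
            ym = y + smid * sy[i]
            new_r = r - ds
            if new_r <= 0.0:
                edep = E  # full residual, including the sub-cutoff remainder
                new_E = 0.0
            else:
                new_E = np.interp(new_r, lay_r, lay_E)
                edep = E - new_E
            ix = int(math.floor((xm + half_x) / pitch_um))
            iy = int(math.floor((ym + half_y) / pitch_um))
            if 0 <= ix < nx and 0 <= iy < ny:
                idx = iy * nx + ix
            else:
                idx = -1
            if idx == prev_idx:
                acc += edep
            else:
                if prev_idx >= 0:
                    esum[prev_idx // nx, prev_idx % nx] += acc
                    esumsq[prev_idx // nx, prev_idx % nx] += acc * acc
                prev_idx = idx
                acc = edep
            total += edep
            if new_r <= 0.0:
                break
            r = new_r
            E = new_E
            s += ds
        if prev_idx >= 0:
            esum[prev_idx // nx, prev_idx % nx] += acc
            esumsq[prev_idx // nx, prev_idx % nx] += acc * acc
        hist_edep[i] = total


def _range_tables_for_stack(stack: LayerStack, effective_charge: bool = True):
    """Range tables for pre-active layers (stacked into rectangular arrays)
    and for the active layer."""
    pre = stack.layers[: stack.active_index]
    tabs = [build_range_table(matl, effective_charge=effective_charge) for matl, _ in pre]
    if tabs:
        pre_E = np.stack([t[0] for t in tabs])
        pre_r = np.stack([t[1] for t in tabs])
    else:
        pre_E = np.zeros((0, 2))
        pre_r = np.zeros((0, 2))
    pre_thick = np.array([t for _, t in pre], dtype=float)
    lay_E, lay_r = build_range_table(stack.active[0], effective_charge=effective_charge)
    return pre_thick, pre_E, pre_r, lay_E, lay_r


@dataclass(frozen=True)
class Particle:
    """A single alpha at the stack entry plane: position (mm), unit
    direction (positive z into the stack), kinetic energy (MeV)."""

    position_mm: tuple[float, float]
    direction: tuple[float, float, float]
    energy_mev: float


def transport_alpha(
    particle: Particle,
    stack: LayerStack,
    pitch_mm: float = 0.01,
    extent_mm: float = 12.0,
    step_um: float = 2.0,
) -> tuple[np.ndarray, float]:
    """Transport one alpha; return (per-voxel deposits MeV, total deposited MeV)."""
    nvox = int(round(extent_mm / pitch_mm))
    esum = np.zeros((nvox, nvox))
    esumsq = np.zeros_like(esum)
    hist = np.zeros(1)
    pre_thick, pre_E, pre_r, lay_E, lay_r = _range_tables_for_stack(stack)
    sx, sy, mu = particle.direction
    _transport_kernel(
        np.array([particle.position_mm[0] * 1e3]),
        np.array([particle.position_mm[1] * 1e3]),
        np.array([sx]),
        np.array([sy]),
        np.array([mu]),
        np.array([particle.energy_mev]),
        pre_thick,
        pre_E,
        pre_r,
        stack.active[1],
        lay_E,
        lay_r,
        nvox,
        nvox,
        pitch_mm * 1e3,
        E_CUT,
        step_um,
        esum,
        esumsq,
        hist,
    )
    return esum, float(hist[0])


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    source: SourceSpec = field(default_factory=SourceSpec)
    stack: LayerStack = field(default_factory=lambda: film_stack("EBT3"))
    pitch_mm: float = 0.01
    extent_mm: float = 12.0
    step_um: float = 2.0
    effective_charge: bool = True


def run_simulation(
    config: SimulationConfig,
    n_histories: int,
    seed: int,
    *,
    chunk: int = 500_000,
    return_history_edep: bool = False,
):
    """Run ``n_histories`` decays; return a :class:`DoseGrid`.

    Each history is one decay: the emission direction is sampled isotropically
    over the full sphere and downward alphas deposit nothing. Deterministic
    (bit-identical) for a fixed seed and configuration.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    nvox = int(round(config.extent_mm / config.pitch_mm))
    esum = np.zeros((nvox, nvox))
    esumsq = np.zeros_like(esum)
    active_mat, t_active = config.stack.active
    if active_mat.density <= 0:
        raise ValueError("zero-mass voxel: active layer density must be > 0")
    pre_thick, pre_E, pre_r, lay_E, lay_r = _range_tables_for_stack(
        config.stack, config.effective_charge
    )
    rng = np.random.default_rng(seed)
    R_um = config.source.active_diameter_mm / 2.0 * 1e3
    energies_grid = np.array([e for e, _ in config.source.spectrum])
    weights = np.array([w for _, w in config.source.spectrum])
    weights = weights / weights.sum()
    hist_all = np.zeros(n_histories) if return_history_edep else None

    done = 0
    while done < n_histories:
        n = min(chunk, n_histories - done)
        r = R_um * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        x0 = r * np.cos(phi)
        y0 = r * np.sin(phi)
        mu = rng.uniform(-1.0, 1.0, n)  # full sphere; mu<=0 absorbed at source
        psi = rng.uniform(0.0, 2.0 * np.pi, n)
        st = np.sqrt(np.maximum(1.0 - mu * mu, 0.0))
        sx = st * np.cos(psi)
        sy = st * np.sin(psi)
        if len(energies_grid) == 1:
            E0 = np.full(n, energies_grid[0])
        else:
            E0 = energies_grid[rng.choice(len(energies_grid), size=n, p=weights)]
        hist = np.zeros(n)
        _transport_kernel(
            x0,
            y0,
            sx,
            sy,
            mu,
            E0,
            pre_thick,
            pre_E,
            pre_r,
            t_active,
            lay_E,
            lay_r,
            nvox,
            nvox,
            config.pitch_mm * 1e3,
            E_CUT,
            config.step_um,
            esum,
            esumsq,
            hist,
        )
        if return_history_edep:
            hist_all[done : done + n] = hist
        done += n

    grid = DoseGrid(
        pitch_mm=config.pitch_mm,
        thickness_um=t_active,
        material=active_mat,
        esum=esum,
        esumsq=esumsq,
        n_histories=n_histories,
        seed=seed,
        medium=config.stack.label,
    )
    if return_history_edep:
        return grid, hist_all
    return grid


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def _roi_mask(grid: DoseGrid, roi_diameter_mm: float) -> np.ndarray:
    x, y = grid.coords_mm()
    X, Y = np.meshgrid(x, y)
    rad = roi_diameter_mm / 2.0
    if rad > grid.nx * grid.pitch_mm / 2.0 or rad > grid.ny * grid.pitch_mm / 2.0:
        raise ValueError("ROI larger than the scoring grid")
    return X * X + Y * Y < rad * rad


def roi_mean_dose_rate(
    grid: DoseGrid,
    roi_diameter_mm: float = 1.0,
    activity_bq: float = 48_000.0,
) -> DoseRateResult:
    """Mean dose rate (Gy/min) over voxels whose centers fall inside the
    central circle, for a source of the given activity.

    The ROI uncertainty treats voxels as independent (mean of per-voxel
    history-by-history uncertainties).
    """
    mask = _roi_mask(grid, roi_diameter_mm)
    dpd = grid.dose_per_decay[mask]
    rel = grid.rel_uncertainty[mask]
    mean_dpd = float(dpd.mean())
    sigma_dpd = float(np.sqrt(np.sum((rel * dpd) ** 2)) / dpd.size)
    factor = activity_bq * 60.0
    return DoseRateResult(
        dose_rate_gy_min=mean_dpd * factor,
        sigma_gy_min=sigma_dpd * factor,
        roi_diameter_mm=roi_diameter_mm,
        medium=grid.medium,
        n_histories=grid.n_histories,
    )


def line_profiles(grid: DoseGrid, roi_result: DoseRateResult) -> dict[str, np.ndarray]:
    """Central-row and central-column dose profiles normalized to the ROI mean.

    Returns a dict with ``x_mm``, ``y_mm``, ``horizontal``, ``vertical`` and
    the matching relative statistical uncertainties.
    """
    x, y = grid.coords_mm()
    dpd = grid.dose_per_decay
    rel = grid.rel_uncertainty
    iy = grid.ny // 2
    ix = grid.nx // 2
    mask = _roi_mask(grid, roi_result.roi_diameter_mm)
    roi_dose_per_decay = float(dpd[mask].mean())
    return {
        "x_mm": x,
        "y_mm": y,
        "horizontal": dpd[iy, :] / roi_dose_per_decay,
        "horizontal_rel_unc": rel[iy, :],
        "vertical": dpd[:, ix] / roi_dose_per_decay,
        "vertical_rel_unc": rel[:, ix],
    }


def percent_difference_vs_water(film: DoseRateResult, water: DoseRateResult) -> float:
    """Percentage increase of the dose rate when film material is replaced by
    water, relative to the water dose rate: 100 * (water - film) / water."""
    return 100.0 * (water.dose_rate_gy_min - film.dose_rate_gy_min) / water.dose_rate_gy_min
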