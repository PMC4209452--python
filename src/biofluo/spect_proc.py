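"""Toy emission-tomography chain.

List-mode energy windowing, triple-energy-window (TEW) scatter
estimation, a parallel-beam projector with an exactly adjoint
backprojector, ordered-subset EM reconstruction, Gaussian
post-filtering and sum projections.

Geometry convention: the volume axes are (x axial, y lateral, z depth,
z pointing downwards from the gel top surface).  The gantry rotates
about the x axis; a projection at angle ``phi`` maps a voxel at
``(y, z)`` to the transaxial detector coordinate
``u = (y - cy) cos(phi) + (z - cz) sin(phi)`` where ``(cy, cz)`` is the
rotation centre, and the axial detector coordinate is ``v = x``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .optical_proc import Image2D, fwhm_to_sigma

__all__ = [
    "EventList",
    "EnergyWindow",
    "ParallelGeometry",
    "SinogramSet",
    "Volume3D",
    "photopeak_window",
    "make_geometry",
    "bin_events",
    "tew_scatter_estimate",
    "subtract_scatter",
    "ParallelProjector",
    "osem_reconstruct",
    "gaussian_postfilter",
    "sum_projection",
]

_EPS = 1e-12


@dataclass
class EventList:
    """List-mode gamma events: projection coordinates plus energy.

    ``is_scatter`` is simulation ground truth carried along for
    validation studies; the processing chain never reads it.
    """

    angle_index: np.ndarray
    u_mm: np.ndarray
    v_mm: np.ndarray
    energy_keV: np.ndarray
    n_angles: int
    is_scatter: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angle_index = np.asarray(self.angle_index, dtype=int)
        self.u_mm = np.asarray(self.u_mm, dtype=float)
        self.v_mm = np.asarray(self.v_mm, dtype=float)
        self.energy_keV = np.asarray(self.energy_keV, dtype=float)
        n = len(self.angle_index)
        if not (len(self.u_mm) == len(self.v_mm) == len(self.energy_keV) == n):
            raise ValueError("event columns must have equal length")
        if n and (self.energy_keV.min() <= 0):
            raise ValueError("energies must be positive")
        if n and (self.angle_index.min() < 0 or self.angle_index.max() >= self.n_angles):
            raise ValueError("angle_index out of range")
        if self.is_scatter is not None:
            self.is_scatter = np.asarray(self.is_scatter, dtype=bool)
            if len(self.is_scatter) != n:
                raise ValueError("is_scatter length mismatch")

    def __len__(self) -> int:
        return len(self.angle_index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "angle_index": self.angle_index,
                "u_mm": self.u_mm,
                "v_mm": self.v_mm,
                "energy_keV": self.energy_keV,
            }
        )
        if self.is_scatter is not None:
            df["is_scatter"] = self.is_scatter.astype(int)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_angles: int) -> "EventList":
        scatter = None
        if "is_scatter" in df.columns:
            scatter = df["is_scatter"].to_numpy().astype(bool)
        return cls(
            df["angle_index"].to_numpy(),
            df["u_mm"].to_numpy(),
            df["v_mm"].to_numpy(),
            df["energy_keV"].to_numpy(),
            n_angles,
            scatter,
        )


@dataclass(frozen=True)
class EnergyWindow:
    lo_keV: float
    hi_keV: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_keV < self.hi_keV:
            raise ValueError("require 0 < lo < hi")

    @property
    def width_keV(self) -> float:
        return self.hi_keV - self.lo_keV

    def contains(self, energy: np.ndarray) -> np.ndarray:
        """Half-open membership test lo <= E < hi."""
        energy = np.asarray(energy)
        return (energy >= self.lo_keV) & (energy < self.hi_keV)


def photopeak_window(peak_keV: float, fraction: float) -> EnergyWindow:
    """Symmetric fractional-width window around a photopeak.

    ``fraction = 0.20`` at 140 keV gives [126, 154] keV.
    """
    if not peak_keV > 0:
        raise ValueError("peak_keV must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    half = peak_keV * fraction / 2.0
    return EnergyWindow(peak_keV - half, peak_keV + half)


@dataclass(frozen=True)
class ParallelGeometry:
    """Parallel-beam binning geometry over a half rotation."""

    n_angles: int
    u_edges: np.ndarray
    v_edges: np.ndarray
    center_y_mm: float = 0.0
    center_z_mm: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "u_edges", np.asarray(self.u_edges, dtype=float))
        object.__setattr__(self, "v_edges", np.asarray(self.v_edges, dtype=float))
        if self.n_angles < 1 or self.nu < 1 or self.nv < 1:
            raise ValueError("geometry must have at least one angle and one bin per axis")
        if np.any(np.diff(self.u_edges) <= 0) or np.any(np.diff(self.v_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def nu(self) -> int:
        return len(self.u_edges) - 1

    @property
    def nv(self) -> int:
        return len(self.v_edges) - 1

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles


def make_geometry(
    n_angles: int,
    nu: int,
    nv: int,
    bin_mm: float,
    *,
    center_y_mm: float = 0.0,
    center_z_mm: float = 0.0,
    v0_mm: float = 0.0,
) -> ParallelGeometry:
    """Uniform geometry: u bins centred on the rotation centre, v bins
    starting at ``v0_mm`` along the axial direction."""
    u_edges = (np.arange(nu + 1) - nu / 2.0) * bin_mm
    v_edges = v0_mm + np.arange(nv + 1) * bin_mm
    return ParallelGeometry(n_angles, u_edges, v_edges, center_y_mm, center_z_mm)


@dataclass
class SinogramSet:
    """Binned counts per (angle, u, v) for one energy window."""

    counts: np.ndarray
    geometry: ParallelGeometry
    window: EnergyWindow
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (self.geometry.n_angles, self.geometry.nu, self.geometry.nv)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != geometry {expected}")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class Volume3D:
    """Isotropic emission volume, axes (x axial, y lateral, z depth)."""

    voxels: np.ndarray
    voxel_size_mm: float
    x_origin_mm: float = 0.0
    center_y_mm: float = 0.0
    center_z_mm: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("voxels must be finite and nonnegative")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bins; the top edge of the last bin is closed."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def bin_events(
    events: EventList, window: EnergyWindow, geometry: ParallelGeometry
) -> SinogramSet:
    """Histogram in-window events onto the projection grid.

    Events inside the energy window but outside the spatial grid are
    dropped and tallied in ``n_discarded`` so that
    ``counts.sum() + n_discarded`` equals the number of in-window events.
    """
    if events.n_angles != geometry.n_angles:
        raise ValueError("event list and geometry disagree on n_angles")
    sel = window.contains(events.energy_keV)
    a = events.angle_index[sel]
    u = events.u_mm[sel]
    v = events.v_mm[sel]
    counts = np.zeros((geometry.n_angles, geometry.nu, geometry.nv))
    if len(a):
        iu = _digitize(u, geometry.u_edges)
        iv = _digitize(v, geometry.v_edges)
        ok = (iu >= 0) & (iu < geometry.nu) & (iv >= 0) & (iv < geometry.nv)
        np.add.at(counts, (a[ok], iu[ok], iv[ok]), 1.0)
        discarded = int(len(a) - ok.sum())
    else:
        discarded = 0
    return SinogramSet(counts, geometry, window, discarded)


def tew_scatter_estimate(
    lower: SinogramSet, upper: SinogramSet, peak_width_keV: float
) -> np.ndarray:
    """Per-bin scatter estimate inside the photopeak window.

    Trapezoidal estimate from the two flanking windows:
    ``(C_low / w_low + C_high / w_high) * w_peak / 2``.
    """
    if lower.counts.shape != upper.counts.shape:
        raise ValueError("background sinograms must share a shape")
    if not peak_width_keV > 0:
        raise ValueError("peak_width_keV must be positive")
    w_low = lower.window.width_keV
    w_high = upper.window.width_keV
    if w_low <= 0 or w_high <= 0:
        raise ValueError("background windows must have positive width")
    return (lower.counts / w_low + upper.counts / w_high) * peak_width_keV / 2.0


def subtract_scatter(peak: SinogramSet, scatter: np.ndarray) -> SinogramSet:
    """Subtract a scatter estimate, clamping corrected counts at zero."""
    scatter = np.asarray(scatter, dtype=float)
    if scatter.shape != peak.counts.shape:
        raise ValueError("scatter estimate shape mismatch")
    corrected = np.maximum(peak.counts - scatter, 0.0)
    return SinogramSet(corrected, peak.geometry, peak.window, peak.n_discarded)


class ParallelProjector:
    """Matched parallel-beam projector / backprojector pair.

    Per angle the projector is stored as a sparse matrix mapping the
    flattened (y, z) voxel plane to u bins with linear interpolation;
    the backprojector is its transpose, so adjointness holds exactly.
    The axial (x) axis maps one-to-one onto v bins, which therefore must
    have the same pitch as the voxels.
    """

    def __init__(
        self, geometry: ParallelGeometry, ny: int, nz: int, voxel_size_mm: float
    ) -> None:
        dv = float(np.diff(geometry.v_edges).mean())
        if not np.isclose(dv, voxel_size_mm, rtol=1e-9):
            raise ValueError("v bin pitch must equal the voxel size")
        self.geometry = geometry
        self.ny, self.nz = ny, nz
        self.nx = geometry.nv
        self.voxel_size_mm = voxel_size_mm
        du = np.diff(geometry.u_edges)
        if not np.allclose(du, du[0]):
            raise ValueError("u bins must be uniform")
        du = float(du[0])
        dy = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size_mm
        dz = (np.arange(nz) - (nz - 1) / 2.0) * voxel_size_mm
        dyg, dzg = np.meshgrid(dy, dz, indexing="ij")
        dyg, dzg = dyg.ravel(), dzg.ravel()
        nu = geometry.nu
        self._mats: list[sp.csr_matrix] = []
        cols = np.arange(ny * nz)
        for phi in geometry.angles_rad:
            u = dyg * np.cos(phi) + dzg * np.sin(phi)
            g = (u - geometry.u_edges[0]) / du - 0.5
            j0 = np.floor(g).astype(int)
            w1 = g - j0
            rows, ccols, data = [], [], []
            for j, w in ((j0, 1.0 - w1), (j0 + 1, w1)):
                ok = (j >= 0) & (j < nu) & (w > 0)
                rows.append(j[ok])
                ccols.append(cols[ok])
                data.append(w[ok])
            mat = sp.coo_matrix(
                (np.concatenate(data), (np.concatenate(rows), np.concatenate(ccols))),
                shape=(nu, ny * nz),
            ).tocsr()
            self._mats.append(mat)

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    def forward(
        self, volume: np.ndarray, angles: Sequence[int] | None = None
    ) -> np.ndarray:
        """Project a volume; returns (n_angles, nu, nv) with zeros at
        angles outside ``angles`` when a subset is given."""
        if volume.shape != self.vol_shape:
            raise ValueError("volume shape mismatch")
        volf = volume.reshape(self.nx, -1).T  # (ny*nz, nx)
        sino = np.zeros((self.geometry.n_angles, self.geometry.nu, self.nx))
        for a in range(self.geometry.n_angles) if angles is None else angles:
            sino[a] = self._mats[a] @ volf
        return sino

    def back(
        self, sinogram: np.ndarray, angles: Sequence[int] | None = None
    ) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        acc = np.zeros((self.ny * self.nz, self.nx))
        for a in range(self.geometry.n_angles) if angles is None else angles:
            acc += self._mats[a].T @ sinogram[a]
        return acc.T.reshape(self.vol_shape)


def osem_reconstruct(
    sinogram: SinogramSet,
    ny: int,
    nz: int,
    voxel_size_mm: float,
    n_subsets: int,
    n_iterations: int,
    initial: np.ndarray | None = None,
) -> Volume3D:
    """Ordered-subset EM over angle-partitioned subsets.

    With one subset this is exactly MLEM.  ``n_subsets`` is clipped to
    the number of angles; voxels with zero sensitivity in a subset are
    masked out of that subset's update.
    """
    if n_subsets < 1 or n_iterations < 1:
        raise ValueError("n_subsets and n_iterations must be >= 1")
    geom = sinogram.geometry
    n_subsets = min(n_subsets, geom.n_angles)
    proj = ParallelProjector(geom, ny, nz, voxel_size_mm)
    subsets = [list(range(s, geom.n_angles, n_subsets)) for s in range(n_subsets)]
    ones = np.ones_like(sinogram.counts)
    sens = [proj.back(ones, a) for a in subsets]
    if any(np.any(s <= 0) for s in sens):
        warnings.warn("zero-sensitivity voxels excluded from OSEM updates")
    x = np.ones(proj.vol_shape) if initial is None else initial.astype(float).copy()
    y = sinogram.counts
    for _ in range(n_iterations):
        for angles, s in zip(subsets, sens):
            p = proj.forward(x, angles)
            ratio = np.zeros_like(p)
            np.divide(y, p, out=ratio, where=p > _EPS)
            # restrict the ratio to the subset's angles
            upd = proj.back(ratio, angles)
            np.divide(x * upd, s, out=x, where=s > 0)
            x[s <= 0] = 0.0
    return Volume3D(
        np.maximum(x, 0.0),
        voxel_size_mm,
        x_origin_mm=float(geom.v_edges[0]),
        center_y_mm=geom.center_y_mm,
        center_z_mm=geom.center_z_mm,
    )


def gaussian_postfilter(volume: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable 3-D Gaussian low-pass filter.

    Reflective boundaries keep the total voxel sum conserved (the
    kernel mass falling off an edge is folded back inside).
    """
    sigma_vox = fwhm_to_sigma(fwhm_mm) / volume.voxel_size_mm
    smoothed = gaussian_filter(volume.voxels, sigma_vox, mode="reflect", truncate=4.0)
    return Volume3D(
        np.maximum(smoothed, 0.0),
        volume.voxel_size_mm,
        volume.x_origin_mm,
        volume.center_y_mm,
        volume.center_z_mm,
    )


_SUM_AXES = {"vertical": 2, "lateral": 1, "axial": 0}


def sum_projection(volume: Volume3D, axis: str) -> Image2D:
    """Collapse a volume along one axis into a 2-D sum image.

    ``vertical`` sums over depth (top view, rows = lateral y, cols =
    axial x); ``lateral`` gives the side view (rows = depth z, cols =
    axial x); ``axial`` looks down the bore (rows = depth z, cols =
    lateral y).  Total intensity is conserved exactly.
    """
    if axis not in _SUM_AXES:
        raise ValueError(f"axis must be one of {sorted(_SUM_AXES)}")
    summed = volume.voxels.sum(axis=_SUM_AXES[axis]).T
    return Image2D(summed, volume.voxel_size_mm, 1.0, "spect_sum")
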