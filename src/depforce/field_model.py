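"""Electro-quasistatic potential over a periodic interdigitated electrode array.

The chip is modelled as a 2D cross-section (x lateral, z vertical) of one
lateral period of an interdigitated (IDT) strip-electrode array: electrodes of
alternating polarity sit at z = 0, buried under a thin oxide passivation
layer, with aqueous medium above.  The electrodes are long parallel strips,
so the field is taken invariant along their length (y) and the Laplace
problem is solved on the (x, z) plane with dielectric-weighted fluxes,
periodic lateral boundaries, a grounded far-top boundary, and homogeneous
Neumann conditions on the exposed gap segments of the bottom plane.

All lengths are micrometres, potentials are volts.  Potentials are stored
RMS-scaled (electrode amplitude divided by sqrt(2)) so that squared-field
quantities computed downstream are time averages of the sinusoidal drive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ElectrodeGeometry",
    "DriveSignal",
    "FieldSolution",
    "DerivativeTensor",
    "solve_potential",
    "plate_capacitor_potential",
    "analytic_coplanar_potential",
    "mixed_partials",
    "mixed_partial_grid",
    "max_interior_residual",
    "save_field",
    "load_field",
    "phi_slice_csv",
]

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

_GRID_TOL = 1e-9


def _snap_to_grid(length: float, h: float, name: str) -> int:
    """Number of grid cells spanned by *length*; must be a near-integer multiple."""
    n = length / h
    if abs(n - round(n)) > 1e-6 * max(1.0, n):
        raise ValueError(
            f"{name} = {length} um is not an integer multiple of the "
            f"grid spacing {h} um"
        )
    return int(round(n))


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Cross-sectional geometry of the IDT chip.

    Defaults follow the reference chip: 40 um wide chromium electrodes with
    10 um gaps under a 0.8 um silicon dioxide passivation layer, immersed in
    water.  ``domain_height`` is where the grounded far-field boundary is
    placed; the lateral period of the alternating-polarity pattern is
    ``2 * (electrode_width + gap)``.
    """

    electrode_width: float = 40.0
    gap: float = 10.0
    oxide_thickness: float = 0.8
    oxide_rel_permittivity: float = 3.9
    medium_rel_permittivity: float = 78.5
    domain_height: float = 100.0
    grid_spacing: float = 0.2

    def __post_init__(self) -> None:
        for name in ("electrode_width", "gap", "domain_height", "grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.oxide_thickness < 0:
            raise ValueError("oxide_thickness must be >= 0")
        if self.oxide_rel_permittivity <= 0 or self.medium_rel_permittivity <= 0:
            raise ValueError("relative permittivities must be > 0")
        if self.grid_spacing > self.gap / 4 + _GRID_TOL:
            raise ValueError(
                f"grid_spacing {self.grid_spacing} um too coarse: must be "
                f"<= gap/4 = {self.gap / 4} um to resolve the gap"
            )
        if self.domain_height < 2 * (self.electrode_width + self.gap) - _GRID_TOL:
            raise ValueError(
                "domain_height must be at least one lateral period "
                f"(2*(width+gap) = {2 * (self.electrode_width + self.gap)} um)"
            )
        # the grid must land exactly on electrode edges and the oxide interface
        h = self.grid_spacing
        _snap_to_grid(self.electrode_width, h, "electrode_width")
        _snap_to_grid(self.gap, h, "gap")
        _snap_to_grid(self.domain_height, h, "domain_height")
        if self.oxide_thickness > 0:
            _snap_to_grid(self.oxide_thickness, h, "oxide_thickness")

    @property
    def period(self) -> float:
        """Lateral period of the alternating-polarity pattern (um)."""
        return 2.0 * (self.electrode_width + self.gap)


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal AC drive applied between adjacent electrodes."""

    frequency: float = 1.0e6
    v_pp: float = 1.0
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.v_pp < 0:
            raise ValueError("v_pp must be >= 0")
        if self.waveform != "sinusoid":
            raise ValueError("only sinusoidal drive is supported")

    @property
    def omega(self) -> float:
        """Angular frequency (rad/s)."""
        return 2.0 * math.pi * self.frequency

    @property
    def amplitude(self) -> float:
        """Peak voltage (V)."""
        return self.v_pp / 2.0

    @property
    def rms(self) -> float:
        """RMS voltage of the drive (V)."""
        return self.v_pp / (2.0 * math.sqrt(2.0))


@dataclass
class FieldSolution:
    """Gridded RMS-scaled potential Phi(x, z) over one electrode period.

    ``phi[i, k]`` is the potential at ``(x_axis[i], z_axis[k])``.  The x axis
    is periodic: node 0 is the left edge of a positive electrode and the node
    after the last one wraps back to it.
    """

    phi: np.ndarray
    x_axis: np.ndarray
    z_axis: np.ndarray
    applied: DriveSignal
    geometry: ElectrodeGeometry
    boundary_note: str = ""
    max_residual: float = 0.0
    _dgrids: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.phi.shape != (self.x_axis.size, self.z_axis.size):
            raise ValueError("phi shape does not match axes")

    @property
    def spacing(self) -> float:
        return float(self.x_axis[1] - self.x_axis[0])

    def scaled(self, v_pp: float) -> "FieldSolution":
        """Same field re-scaled to a different peak-to-peak voltage (linearity)."""
        if self.applied.v_pp == 0:
            raise ValueError("cannot rescale a zero-voltage solution")
        factor = v_pp / self.applied.v_pp
        return FieldSolution(
            phi=self.phi * factor,
            x_axis=self.x_axis,
            z_axis=self.z_axis,
            applied=replace(self.applied, v_pp=v_pp),
            geometry=self.geometry,
            boundary_note=self.boundary_note,
            max_residual=self.max_residual * abs(factor),
        )

    def sample(self, grid: np.ndarray, point) -> float:
        """Bilinear sample of any co-gridded array at (x, z), x wrapped periodically."""
        x, z = float(point[0]), float(point[1])
        h = self.spacing
        period = self.geometry.period
        x = x % period
        z0, z1 = float(self.z_axis[0]), float(self.z_axis[-1])
        if not (z0 - _GRID_TOL <= z <= z1 + _GRID_TOL):
            raise ValueError(f"point z={z} outside domain [{z0}, {z1}]")
        nx = self.x_axis.size
        fx = x / h
        ix = int(math.floor(fx))
        tx = fx - ix
        ix0, ix1 = ix % nx, (ix + 1) % nx
        fz = min(max((z - z0) / h, 0.0), self.z_axis.size - 1.0)
        iz = min(int(math.floor(fz)), self.z_axis.size - 2)
        tz = fz - iz
        v00 = grid[ix0, iz]
        v10 = grid[ix1, iz]
        v01 = grid[ix0, iz + 1]
        v11 = grid[ix1, iz + 1]
        return float(
            (1 - tx) * (1 - tz) * v00
            + tx * (1 - tz) * v10
            + (1 - tx) * tz * v01
            + tx * tz * v11
        )


@dataclass(frozen=True)
class DerivativeTensor:
    """All mixed partial derivatives of Phi of one order at a point.

    ``components`` maps index triples ``(i, j, k)`` with ``i + j + k == order``
    to the value of d^n Phi / dx^i dy^j dz^k in V/um^n.  For 2D fields every
    component with j > 0 is exactly zero.
    """

    order: int
    point: tuple
    components: dict

    def __post_init__(self) -> None:
        for (i, j, k) in self.components:
            if i + j + k != self.order or min(i, j, k) < 0:
                raise ValueError(f"bad index triple {(i, j, k)} for order {self.order}")

    def __getitem__(self, triple):
        return self.components[triple]


# ---------------------------------------------------------------------------
# core sparse solve
# ---------------------------------------------------------------------------

def _core_solve(eps_x: np.ndarray, eps_z: np.ndarray,
                dirichlet_mask: np.ndarray, dirichlet_values: np.ndarray) -> np.ndarray:
    """Solve div(eps grad phi) = 0 on a uniform (Nx, Nz) grid.

    x is periodic; z = top row must be Dirichlet; non-Dirichlet bottom nodes
    get a zero-flux (mirror) condition.  ``eps_x[i, k]`` weights the face
    between nodes (i, k) and (i+1 mod Nx, k); ``eps_z[i, k]`` the face between
    (i, k) and (i, k+1).  Returns phi with shape (Nx, Nz).
    """
    nx, nz = dirichlet_mask.shape
    n = nx * nz

    def flat(i, k):
        return i * nz + k

    ii = np.repeat(np.arange(nx), nz)
    kk = np.tile(np.arange(nz), nx)
    center = flat(ii, kk)

    rows, cols, vals = [], [], []

    def add(coeff, nbr_idx, valid):
        rows.append(center[valid])
        cols.append(nbr_idx[valid])
        vals.append(coeff[valid])

    free = ~dirichlet_mask[ii, kk]

    # east / west couplings (periodic wrap)
    ce = eps_x[ii, kk]
    cw = eps_x[(ii - 1) % nx, kk]
    east = flat((ii + 1) % nx, kk)
    west = flat((ii - 1) % nx, kk)
    # north / south; bottom mirror doubles the north coupling
    cn = np.zeros(n)
    has_n = kk < nz - 1
    cn[has_n] = eps_z[ii[has_n], kk[has_n]]
    cn[kk == 0] *= 2.0
    cs = np.zeros(n)
    has_s = kk > 0
    cs[has_s] = eps_z[ii[has_s], kk[has_s] - 1]
    north = flat(ii, np.minimum(kk + 1, nz - 1))
    south = flat(ii, np.maximum(kk - 1, 0))

    add(ce, east, free)
    add(cw, west, free)
    add(cn, north, free & has_n)
    add(cs, south, free & has_s)
    diag = -(ce + cw + cn + cs)
    add(diag, center, free)

    # Dirichlet rows: identity
    fixed = ~free
    rows.append(center[fixed])
    cols.append(center[fixed])
    vals.append(np.ones(fixed.sum()))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b = np.zeros(n)
    b[center[fixed]] = dirichlet_values[ii[fixed], kk[fixed]]

    phi = spla.spsolve(A.tocsc(), b)
    return phi.reshape(nx, nz)


def _face_permittivities(geom: ElectrodeGeometry, nx: int, nz: int) -> tuple:
    """Relative permittivity on x- and z-faces of the grid."""
    h = geom.grid_spacing
    z_nodes = np.arange(nz) * h
    e_ox, e_m = geom.oxide_rel_permittivity, geom.medium_rel_permittivity
    t = geom.oxide_thickness
    # horizontal flux at node height: oxide below interface, medium above,
    # arithmetic mean exactly on the interface node (half-in-half)
    eps_at_node = np.where(z_nodes < t - _GRID_TOL, e_ox, e_m)
    on_iface = np.abs(z_nodes - t) < _GRID_TOL
    eps_at_node = np.where(on_iface, 0.5 * (e_ox + e_m), eps_at_node)
    if t <= _GRID_TOL:
        eps_at_node = np.full(nz, e_m)
        eps_at_node[0] = e_m  # bare-electrode limit: all medium
    eps_x = np.broadcast_to(eps_at_node, (nx, nz)).copy()
    # vertical flux between node k and k+1 uses the layer at the face midpoint
    z_faces = (np.arange(nz - 1) + 0.5) * h
    eps_face = np.where(z_faces < t, e_ox, e_m)
    eps_z = np.broadcast_to(eps_face, (nx, nz - 1)).copy()
    return eps_x, eps_z


def _electrode_bottom_mask(geom: ElectrodeGeometry, nx: int):
    """Boolean masks of bottom-row nodes on the + and - electrodes."""
    h = geom.grid_spacing
    x = np.arange(nx) * h
    w, g = geom.electrode_width, geom.gap
    pos = x <= w + _GRID_TOL
    neg = (x >= w + g - _GRID_TOL) & (x <= 2 * w + g + _GRID_TOL)
    return pos, neg


def solve_potential(geometry: ElectrodeGeometry, signal: DriveSignal) -> FieldSolution:
    """Solve for the RMS-scaled potential over one IDT period.

    Alternating electrodes are held at plus/minus half the RMS drive voltage
    (i.e. ``+-v_pp / (4 sqrt 2)``), the top boundary is grounded, the lateral
    boundaries are periodic, and the exposed gap segments of the bottom plane
    carry zero normal flux.  The oxide/medium interface is honoured through
    face permittivities (flux continuity).

    The unit-potential problem is solved once and scaled by the drive, so the
    solution is exactly linear in ``v_pp``.
    """
    h = geometry.grid_spacing
    nx = _snap_to_grid(geometry.period, h, "period")
    nz = _snap_to_grid(geometry.domain_height, h, "domain_height") + 1
    x_axis = np.arange(nx) * h
    z_axis = np.arange(nz) * h

    eps_x, eps_z = _face_permittivities(geometry, nx, nz)
    dirichlet = np.zeros((nx, nz), dtype=bool)
    values = np.zeros((nx, nz))
    pos, neg = _electrode_bottom_mask(geometry, nx)
    dirichlet[pos, 0] = True
    values[pos, 0] = 1.0
    dirichlet[neg, 0] = True
    values[neg, 0] = -1.0
    dirichlet[:, -1] = True  # grounded top

    unit_phi = _core_solve(eps_x, eps_z, dirichlet, values)
    scale = signal.rms / 2.0  # electrodes at +- rms/2
    phi = unit_phi * scale

    sol = FieldSolution(
        phi=phi,
        x_axis=x_axis,
        z_axis=z_axis,
        applied=signal,
        geometry=geometry,
        boundary_note=(
            "periodic in x; electrodes at +-v_pp/(4*sqrt(2)) (RMS convention); "
            "grounded top at z=domain_height; zero normal flux on gap segments"
        ),
    )
    res = max_interior_residual(sol)
    sol.max_residual = res
    peak = np.abs(phi).max()
    if peak > 0 and res > 1e-6 * peak:
        raise RuntimeError(
            f"field solve did not meet the residual tolerance: "
            f"max residual {res:.3e} vs limit {1e-6 * peak:.3e}"
        )
    return sol


def plate_capacitor_potential(v_top: float, height: float = 20.0,
                              width: float = 20.0, grid_spacing: float = 0.5,
                              rel_permittivity: float = 1.0) -> FieldSolution:
    """Uniform-permittivity parallel-plate fixture: top plate at ``v_top``, bottom at 0.

    Exercises the same discrete operator as :func:`solve_potential`; the exact
    solution is linear in z, so it validates the assembly end to end.
    """
    h = grid_spacing
    nx = _snap_to_grid(width, h, "width")
    nz = _snap_to_grid(height, h, "height") + 1
    eps_x = np.full((nx, nz), rel_permittivity)
    eps_z = np.full((nx, nz - 1), rel_permittivity)
    dirichlet = np.zeros((nx, nz), dtype=bool)
    values = np.zeros((nx, nz))
    dirichlet[:, 0] = True
    dirichlet[:, -1] = True
    values[:, -1] = v_top
    phi = _core_solve(eps_x, eps_z, dirichlet, values)
    # A FieldSolution wants an ElectrodeGeometry; the plate fixture is not an
    # IDT chip, so return the raw pieces in a lightweight namespace instead.
    from types import SimpleNamespace

    return SimpleNamespace(
        phi=phi,
        x_axis=np.arange(nx) * h,
        z_axis=np.arange(nz) * h,
        boundary_note="plate-capacitor fixture",
    )


def analytic_coplanar_potential(geometry: ElectrodeGeometry, signal: DriveSignal,
                                n_harmonics: int = 200) -> FieldSolution:
    """Fourier-series half-space potential for bare coplanar strip electrodes.

    Validation oracle for :func:`solve_potential`: the oxide is ignored
    (treated as zero thickness) and the boundary potential across each gap is
    taken linear between the neighbouring electrode potentials.  Each lateral
    Fourier mode m of the z = 0 profile decays as ``exp(-2 pi m z / period)``,
    which is the exact harmonic extension into the upper half space.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    h = geometry.grid_spacing
    period = geometry.period
    nx = _snap_to_grid(period, h, "period")
    nz = _snap_to_grid(geometry.domain_height, h, "domain_height") + 1
    x = np.arange(nx) * h
    z = np.arange(nz) * h

    amp = signal.rms / 2.0
    w, g = geometry.electrode_width, geometry.gap
    profile = np.zeros(nx)
    for xi in range(nx):
        xx = x[xi]
        if xx <= w + _GRID_TOL:
            profile[xi] = amp
        elif xx < w + g - _GRID_TOL:
            profile[xi] = amp * (1.0 - 2.0 * (xx - w) / g)
        elif xx <= 2 * w + g + _GRID_TOL:
            profile[xi] = -amp
        else:
            profile[xi] = -amp * (1.0 - 2.0 * (xx - (2 * w + g)) / g)

    coeff = np.fft.rfft(profile) / nx
    m_max = min(n_harmonics, coeff.size - 1)
    phi = np.zeros((nx, nz))
    for m in range(1, m_max + 1):
        cm = coeff[m]
        mode = 2.0 * (cm.real * np.cos(2 * np.pi * m * x / period)
                      - cm.imag * np.sin(2 * np.pi * m * x / period))
        decay = np.exp(-2 * np.pi * m * z / period)
        phi += np.outer(mode, decay)
    phi += coeff[0].real  # mean term (zero for the symmetric drive)

    return FieldSolution(
        phi=phi,
        x_axis=x,
        z_axis=z,
        applied=signal,
        geometry=geometry,
        boundary_note=(
            f"analytic half-space Fourier series, {m_max} harmonics, "
            "oxide ignored, linear gap interpolation"
        ),
    )


def max_interior_residual(sol: FieldSolution) -> float:
    """Max dielectric-weighted discrete flux divergence over interior nodes (V)."""
    geom = sol.geometry
    nx, nz = sol.phi.shape
    eps_x, eps_z = _face_permittivities(geom, nx, nz)
    phi = sol.phi
    east = np.roll(phi, -1, axis=0)
    west = np.roll(phi, 1, axis=0)
    inner = phi[:, 1:-1]
    res = (
        eps_x[:, 1:-1] * (east[:, 1:-1] - inner)
        + np.roll(eps_x, 1, axis=0)[:, 1:-1] * (west[:, 1:-1] - inner)
        + eps_z[:, 1:] * (phi[:, 2:] - inner)
        + eps_z[:, :-1] * (phi[:, :-2] - inner)
    )
    scale = max(geom.oxide_rel_permittivity, geom.medium_rel_permittivity) * 4.0
    return float(np.abs(res).max() / scale)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def mixed_partial_grid(sol: FieldSolution, i: int, k: int) -> np.ndarray:
    """Grid of d^(i+k) Phi / dx^i dz^k (V/um^n) by nested central differences.

    The x direction is differentiated with periodic wrap padding so no lateral
    edge artefacts appear; z edges fall back to numpy's one-sided second-order
    stencils.  Results are cached on the solution object.
    """
    key = (i, k)
    if key in sol._dgrids:
        return sol._dgrids[key]
    order = i + k
    if order < 0 or (i < 0 or k < 0):
        raise ValueError("derivative orders must be non-negative")
    h = sol.spacing
    pad = max(order, 1)
    arr = np.concatenate([sol.phi[-pad:], sol.phi, sol.phi[:pad]], axis=0)
    for _ in range(i):
        arr = np.gradient(arr, h, axis=0)
    for _ in range(k):
        arr = np.gradient(arr, h, axis=1)
    out = np.ascontiguousarray(arr[pad:-pad])
    sol._dgrids[key] = out
    return out


def _index_triples(order: int):
    for i in range(order + 1):
        for j in range(order + 1 - i):
            k = order - i - j
            yield (i, j, k)


def mixed_partials(sol: FieldSolution, order: int, point) -> DerivativeTensor:
    """All mixed partials of Phi of the given order at (x, z), in V/um^order.

    The solution is 2D (invariant along the electrode length y), so every
    component with a y index j > 0 is exactly zero.
    """
    if not 1 <= order <= 4:
        raise ValueError("order must be between 1 and 4")
    h = sol.spacing
    z = float(point[1])
    margin = order * h
    if z < sol.z_axis[0] + margin - _GRID_TOL or z > sol.z_axis[-1] - margin + _GRID_TOL:
        raise ValueError(
            f"point z={z} is within {order} stencil widths of a z boundary"
        )
    comps = {}
    for (i, j, k) in _index_triples(order):
        if j > 0:
            comps[(i, j, k)] = 0.0
        else:
            grid = mixed_partial_grid(sol, i, k)
            comps[(i, j, k)] = sol.sample(grid, point)
    return DerivativeTensor(order=order, point=(float(point[0]), z), components=comps)


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def save_field(sol: FieldSolution, path) -> None:
    """Write the gridded field plus metadata to an .npz archive."""
    meta = {
        "geometry": sol.geometry.__dict__,
        "signal": {"frequency": sol.applied.frequency,
                   "v_pp": sol.applied.v_pp,
                   "waveform": sol.applied.waveform},
        "boundary_note": sol.boundary_note,
        "max_residual": sol.max_residual,
    }
    np.savez_compressed(
        path, phi=sol.phi, x_axis=sol.x_axis, z_axis=sol.z_axis,
        meta=np.array(json.dumps(meta)),
    )


def load_field(path) -> FieldSolution:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        sol = FieldSolution(
            phi=data["phi"],
            x_axis=data["x_axis"],
            z_axis=data["z_axis"],
            applied=DriveSignal(**meta["signal"]),
            geometry=ElectrodeGeometry(**meta["geometry"]),
            boundary_note=meta["boundary_note"],
            max_residual=meta.get("max_residual", 0.0),
        )
    return sol


def phi_slice_csv(sol: FieldSolution, z: float, path) -> None:
    """Export the potential along a horizontal line at height z as CSV."""
    import pandas as pd

    vals = [sol.sample(sol.phi, (x, z)) for x in sol.x_axis]
    pd.DataFrame({"x_um": sol.x_axis, "phi_V": vals}).to_csv(path, index=False)
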