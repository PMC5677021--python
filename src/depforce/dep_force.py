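"""Multipolar dielectrophoretic forces on a spherical microparticle.

The time-averaged DEP interaction of a sphere with a non-uniform AC field is
expanded in multipole order n.  Each order contributes an energy

    U_n = -[2 pi eps_m Re(K_n) r^(2n+1) / (2n+1)!!]
          * sum_{i+j+k=n} (1/(i! j! k!)) [d^n Phi / dx^i dy^j dz^k]^2

with the order-n Clausius-Mossotti factor

    K_n = n (2n+1) (ep - em) / (n ep + (n+1) em)

in complex permittivities e = eps_r - i sigma / (eps0 omega).  The total
force is F = sum_n -grad U_n.  The n = 1 term reproduces the classical
dipole DEP formula F = 2 pi eps_m r^3 Re(CM) grad |E_rms|^2 since K_1 = 3 CM.

Potentials come in RMS-scaled from :mod:`depforce.field_model`, so all
energies and forces here are time averages.  Forces are reported in pN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from depforce.field_model import (
    EPS0,
    DriveSignal,
    FieldSolution,
    mixed_partial_grid,
)

__all__ = [
    "MediumProperties",
    "ParticleProperties",
    "MultipoleExpansion",
    "ForceResult",
    "ForceMap",
    "CalibrationResult",
    "clausius_mossotti_order",
    "classical_cm_factor",
    "multipole_energy",
    "multipole_energy_map",
    "total_dep_force",
    "force_map",
    "classical_dipole_force_map",
    "voltage_force_calibration",
    "rest_position",
]


@dataclass(frozen=True)
class MediumProperties:
    """Suspending medium. Defaults: DI water (eps_r 78.5, sigma 2e-4 S/m)."""

    rel_permittivity: float = 78.5
    conductivity: float = 2.0e-4

    def __post_init__(self) -> None:
        if self.rel_permittivity <= 0:
            raise ValueError("rel_permittivity must be > 0")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")

    def complex_permittivity(self, omega: float) -> complex:
        """Relative complex permittivity eps_r - i sigma/(eps0 omega)."""
        return self.rel_permittivity - 1j * self.conductivity / (EPS0 * omega)


@dataclass(frozen=True)
class ParticleProperties:
    """Spherical probe particle. Defaults: 15 um polystyrene bead.

    The conductivity default is a surface-conductance proxy for a
    carboxylated bead; at 1 MHz in water the dielectric contrast dominates
    and Re(K_1) < 0 (negative DEP) regardless.
    """

    radius: float = 7.5  # um
    rel_permittivity: float = 2.55
    conductivity: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.rel_permittivity <= 0:
            raise ValueError("rel_permittivity must be > 0")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")

    def complex_permittivity(self, omega: float) -> complex:
        return self.rel_permittivity - 1j * self.conductivity / (EPS0 * omega)


@dataclass
class MultipoleExpansion:
    """Per-order factors and energies of the multipole series at one point."""

    n_max: int
    k_factors: list          # complex K_n, n = 1..n_max
    per_order_energy: list   # U_n (J) at the evaluation point
    convergence_ratio: float # |F_n_max| / |F_total|


@dataclass
class ForceResult:
    """Total DEP force and its per-order decomposition at a point."""

    point: tuple                 # (x, z) um
    force: np.ndarray            # (Fx, Fz) pN
    per_order_force: list        # list of (Fx, Fz) pN arrays, order 1..n_max
    voltage: DriveSignal
    expansion: MultipoleExpansion
    converged: bool = True


@dataclass
class ForceMap:
    """Gridded per-order and total DEP force over the field solution.

    ``fx``/``fz`` are (n_max, Nx, Nz) arrays in pN; ``valid`` masks nodes far
    enough from the z boundaries for all stencils involved.
    """

    field: FieldSolution
    fx: np.ndarray
    fz: np.ndarray
    valid: np.ndarray
    n_max: int

    @property
    def total_fx(self) -> np.ndarray:
        return self.fx.sum(axis=0)

    @property
    def total_fz(self) -> np.ndarray:
        return self.fz.sum(axis=0)

    def to_dataframe(self):
        """Long-format table (x, z, Fx, Fz, per-order columns), valid nodes only."""
        import pandas as pd

        xs, zs = np.meshgrid(self.field.x_axis, self.field.z_axis, indexing="ij")
        m = self.valid
        data = {"x_um": xs[m], "z_um": zs[m],
                "fx_pN": self.total_fx[m], "fz_pN": self.total_fz[m]}
        for n in range(self.n_max):
            data[f"fx_n{n + 1}_pN"] = self.fx[n][m]
            data[f"fz_n{n + 1}_pN"] = self.fz[n][m]
        return pd.DataFrame(data)


@dataclass
class CalibrationResult:
    """Force-voltage calibration F(V_pp) = c * V_pp^2 at the bead rest position."""

    c: float                  # pN per V_pp^2 (magnitude of vertical force)
    point: tuple              # (x, z) um
    n_max: int
    convergence_ratio: float
    upward: bool              # True if the vertical force points away from the chip
    warning: str = ""

    def force_at(self, v_pp: float) -> float:
        return self.c * v_pp ** 2

    def report(self) -> str:
        lines = [
            "DEP force-voltage calibration",
            f"  c = {self.c:.6g} pN per V_pp^2",
            f"  evaluation point = ({self.point[0]:.3g}, {self.point[1]:.3g}) um",
            f"  n_max = {self.n_max}",
            f"  convergence ratio |F_nmax|/|F_total| = {self.convergence_ratio:.3g}",
            f"  vertical direction = {'upward (rupturing)' if self.upward else 'downward'}",
        ]
        if self.warning:
            lines.append(f"  warning: {self.warning}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Clausius-Mossotti factors
# ---------------------------------------------------------------------------

def clausius_mossotti_order(n: int, medium: MediumProperties,
                            particle: ParticleProperties,
                            signal: DriveSignal) -> complex:
    """Order-n Clausius-Mossotti factor K_n = n(2n+1)(ep-em)/(n ep + (n+1) em)."""
    if n < 1:
        raise ValueError("multipole order n must be >= 1")
    ep = particle.complex_permittivity(signal.omega)
    em = medium.complex_permittivity(signal.omega)
    den = n * ep + (n + 1) * em
    if abs(den) < 1e-30 * max(abs(ep), abs(em), 1.0):
        raise ZeroDivisionError(
            f"degenerate permittivity combination: n*ep + (n+1)*em vanishes "
            f"at order {n} (ep={ep}, em={em})"
        )
    return n * (2 * n + 1) * (ep - em) / den


def classical_cm_factor(medium: MediumProperties, particle: ParticleProperties,
                        signal: DriveSignal) -> complex:
    """Classical dipole Clausius-Mossotti factor (ep - em)/(ep + 2 em) = K_1 / 3."""
    ep = particle.complex_permittivity(signal.omega)
    em = medium.complex_permittivity(signal.omega)
    return (ep - em) / (ep + 2 * em)


# ---------------------------------------------------------------------------
# multipole energies and forces
# ---------------------------------------------------------------------------

def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _energy_prefactor(n: int, medium: MediumProperties,
                      particle: ParticleProperties, signal: DriveSignal) -> float:
    """-2 pi eps_m Re(K_n) r^(2n+1) / (2n+1)!! in SI (J per (V/m)^2 ... m^2n)."""
    kn = clausius_mossotti_order(n, medium, particle, signal)
    eps_m = EPS0 * medium.rel_permittivity
    r_m = particle.radius * 1e-6
    return -2.0 * math.pi * eps_m * kn.real * r_m ** (2 * n + 1) / _double_factorial(2 * n + 1)


def multipole_energy_map(sol: FieldSolution, medium: MediumProperties,
                         particle: ParticleProperties, n: int) -> np.ndarray:
    """Grid of the order-n multipole energy U_n (J) over the field solution."""
    if n < 1:
        raise ValueError("multipole order n must be >= 1")
    pref = _energy_prefactor(n, medium, particle, sol.applied)
    # 2D field: only j = 0 terms survive; derivatives converted V/um^n -> V/m^n
    total = np.zeros_like(sol.phi)
    unit = 1e6 ** n
    for i in range(n + 1):
        k = n - i
        d = mixed_partial_grid(sol, i, k) * unit
        total += d * d / (math.factorial(i) * math.factorial(k))
    return pref * total


def multipole_energy(sol: FieldSolution, medium: MediumProperties,
                     particle: ParticleProperties, n: int, point) -> float:
    """Order-n multipole energy U_n (J) at a point (bilinear sample of the map)."""
    h = sol.spacing
    z = float(point[1])
    margin = n * h
    if z < sol.z_axis[0] + margin - 1e-9 or z > sol.z_axis[-1] - margin + 1e-9:
        raise ValueError(f"point z={z} too close to a z boundary for order-{n} stencils")
    umap = multipole_energy_map(sol, medium, particle, n)
    return sol.sample(umap, point)


def _grad_periodic(grid: np.ndarray, h_m: float) -> tuple:
    """Gradient of a co-gridded scalar, periodic in x, spacing h_m (metres)."""
    pad = 1
    arr = np.concatenate([grid[-pad:], grid, grid[:pad]], axis=0)
    gx = np.gradient(arr, h_m, axis=0)[pad:-pad]
    gz = np.gradient(grid, h_m, axis=1)
    return gx, gz


def force_map(sol: FieldSolution, medium: MediumProperties,
              particle: ParticleProperties, n_max: int = 3) -> ForceMap:
    """Per-order DEP force F_n = -grad U_n on every grid node, in pN.

    Nodes within ``n_max + 1`` stencil widths of the top/bottom boundaries are
    masked out (``valid = False``); x is periodic, so no lateral masking.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    h_m = sol.spacing * 1e-6
    nx, nz = sol.phi.shape
    fx = np.zeros((n_max, nx, nz))
    fz = np.zeros((n_max, nx, nz))
    for n in range(1, n_max + 1):
        u = multipole_energy_map(sol, medium, particle, n)
        gx, gz = _grad_periodic(u, h_m)
        fx[n - 1] = -gx * 1e12  # N -> pN
        fz[n - 1] = -gz * 1e12
    valid = np.zeros((nx, nz), dtype=bool)
    margin = n_max + 1
    valid[:, margin:nz - margin] = True
    return ForceMap(field=sol, fx=fx, fz=fz, valid=valid, n_max=n_max)


def total_dep_force(sol: FieldSolution, medium: MediumProperties,
                    particle: ParticleProperties, n_max: int, point,
                    fmap: ForceMap | None = None) -> ForceResult:
    """Total DEP force (pN) at a point, with its per-order decomposition.

    Flags ``converged = False`` when per-order force magnitudes fail to
    decrease up to ``n_max`` (the multipole series is not converging for this
    bead size / field sharpness at that point).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if fmap is None or fmap.n_max < n_max:
        fmap = force_map(sol, medium, particle, n_max)
    per_order = []
    energies = []
    for n in range(1, n_max + 1):
        f = np.array([sol.sample(fmap.fx[n - 1], point),
                      sol.sample(fmap.fz[n - 1], point)])
        per_order.append(f)
        energies.append(multipole_energy(sol, medium, particle, n, point))
    total = np.sum(per_order, axis=0)
    mags = [float(np.hypot(*f)) for f in per_order]
    tot_mag = float(np.hypot(*total))
    conv_ratio = mags[-1] / tot_mag if tot_mag > 0 else 0.0
    converged = all(mags[i + 1] <= mags[i] or mags[i + 1] < 1e-12 * tot_mag
                    for i in range(len(mags) - 1))
    if not converged:
        warnings.warn(
            f"multipole series not converging at point {tuple(point)}: "
            f"per-order force magnitudes {mags}", RuntimeWarning, stacklevel=2)
    kf = [clausius_mossotti_order(n, medium, particle, sol.applied)
          for n in range(1, n_max + 1)]
    exp = MultipoleExpansion(n_max=n_max, k_factors=kf,
                             per_order_energy=energies,
                             convergence_ratio=conv_ratio)
    return ForceResult(point=(float(point[0]), float(point[1])), force=total,
                       per_order_force=per_order, voltage=sol.applied,
                       expansion=exp, converged=converged)


def classical_dipole_force_map(sol: FieldSolution, medium: MediumProperties,
                               particle: ParticleProperties) -> tuple:
    """Classical dipole DEP force map F = 2 pi eps_m r^3 Re(CM) grad |E_rms|^2.

    Independent of the multipole-energy machinery (no K_n, no factorial sums):
    used as a cross-check oracle for the n_max = 1 restriction of
    :func:`force_map`.  Returns (fx, fz) grids in pN.
    """
    h_m = sol.spacing * 1e-6
    cm = classical_cm_factor(medium, particle, sol.applied)
    pref = 2.0 * math.pi * EPS0 * medium.rel_permittivity * (particle.radius * 1e-6) ** 3 * cm.real
    ex, ez = _grad_periodic(sol.phi, h_m)   # grad Phi, V/m
    e2 = ex * ex + ez * ez                  # |E_rms|^2
    gx, gz = _grad_periodic(e2, h_m)
    return pref * gx * 1e12, pref * gz * 1e12


def rest_position(geometry, particle: ParticleProperties) -> tuple:
    """Default bead-centre rest position: over the positive-electrode
    centerline, one radius above the oxide surface."""
    x = geometry.electrode_width / 2.0
    z = geometry.oxide_thickness + particle.radius
    return (x, z)


def voltage_force_calibration(sol: FieldSolution, medium: MediumProperties,
                              particle: ParticleProperties, n_max: int = 3,
                              point=None) -> CalibrationResult:
    """Calibration c such that the vertical DEP force is F(V_pp) = c * V_pp^2.

    Evaluated by default at the bead rest position (electrode centerline,
    oxide surface + bead radius).  Because the field is linear in the drive,
    the quadratic law is exact; c is reported as the magnitude of the
    vertical (rupturing) force component per squared peak-to-peak volt.
    """
    if point is None:
        point = rest_position(sol.geometry, particle)
    warning = ""
    if sol.applied.v_pp == 0 or np.abs(sol.phi).max() == 0:
        return CalibrationResult(c=0.0, point=tuple(point), n_max=n_max,
                                 convergence_ratio=0.0, upward=True,
                                 warning="zero field: calibration is 0")
    res = total_dep_force(sol, medium, particle, n_max, point)
    fz = float(res.force[1])
    c = abs(fz) / sol.applied.v_pp ** 2
    if not res.converged:
        warning = "multipole series not converging at the evaluation point"
    return CalibrationResult(c=c, point=tuple(point), n_max=n_max,
                             convergence_ratio=res.expansion.convergence_ratio,
                             upward=fz >= 0, warning=warning)
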