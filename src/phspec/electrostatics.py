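"""Finite-difference Poisson-Boltzmann electrostatics.

Solves the (linear or nonlinear) Poisson-Boltzmann equation on a
uniform cubic-voxel grid around a structure and reports potentials in
kT/e at 298 K.  The dielectric is two-valued: solute inside the
probe-inflated atom spheres, solvent outside (no reentrant surface);
ionic screening acts only in the solvent region; grid faces carry a
Debye-Hückel boundary condition summed over all charges.  The
discretized equations are relaxed with checkerboard successive
over-relaxation; the nonlinear mode applies a Newton linearization of
the sinh term at every sweep.

Unit system: lengths in Å, charges in elementary charges, potential
phi in kT/e.  The PB equation then reads

    div(eps grad phi) - kbar^2 sinh(phi) = -4 pi C sum_i q_i delta_i

with C = e^2 / (4 pi eps0 kT Å) ~ 560.7 (so that a point charge q in a
uniform dielectric eps gives phi = C q / (eps r)) and, for a 1:1
electrolyte of molar ionic strength I,
kbar^2 = 8 pi C N_A I 1e-27 Å^-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import constants, ndimage

from .structure import Structure

TEMPERATURE = 298.0  # K, pins the kT/e unit

#: e^2/(4 pi eps0 kT) expressed in kT * Å per e^2 at 298 K
COULOMB_KT = (
    constants.e**2
    / (4.0 * np.pi * constants.epsilon_0 * constants.k * TEMPERATURE)
    / 1e-10
)

#: kbar^2 prefactor per molar ionic strength (Å^-2 / M)
KAPPA2_PER_MOLAR = 8.0 * np.pi * COULOMB_KT * constants.N_A * 1e-27

POTENTIAL_CLAMP = 10.0  # kT/e, display clamp used for surface colouring


# --------------------------------------------------------------- charges

@dataclass(frozen=True)
class ChargeAssignment:
    """Per-atom partial charges in elementary-charge units."""

    charges: np.ndarray
    scheme: str

    @property
    def total(self) -> float:
        return float(np.sum(self.charges))


def assign_charges(
    structure: Structure,
    scheme: str | Path = "formal",
) -> ChargeAssignment:
    """Assign partial charges to the protein atoms of a structure.

    The default ``formal`` scheme places whole formal charges on the
    titratable groups at neutral pH: +1 on Lys NZ and Arg CZ, -0.5 on
    each Asp OD1/OD2 and Glu OE1/OE2 carboxylate oxygen, +1 on each
    chain's N-terminal nitrogen and -0.5 on each C-terminal carboxylate
    oxygen; His is neutral.  Any other ``scheme`` is read as a
    whitespace-delimited table of ``residue atom charge`` rows; atoms
    absent from the table get charge 0 with a warning (once per table).
    """
    n = len(structure)
    q = np.zeros(n)
    if scheme == "formal":
        prot = ~structure.is_hetero
        # chain termini among protein atoms
        first_res: dict[str, int] = {}
        last_res: dict[str, int] = {}
        for i in np.flatnonzero(prot):
            c = structure.chain_ids[i]
            s = int(structure.res_seq[i])
            first_res[c] = min(first_res.get(c, s), s)
            last_res[c] = max(last_res.get(c, s), s)
        for i in np.flatnonzero(prot):
            res = structure.res_names[i].upper()
            atom = structure.atom_names[i].upper()
            c = structure.chain_ids[i]
            s = int(structure.res_seq[i])
            if res == "LYS" and atom == "NZ":
                q[i] += 1.0
            elif res == "ARG" and atom == "CZ":
                q[i] += 1.0
            elif res == "ASP" and atom in ("OD1", "OD2"):
                q[i] -= 0.5
            elif res == "GLU" and atom in ("OE1", "OE2"):
                q[i] -= 0.5
            if atom == "N" and s == first_res[c]:
                q[i] += 1.0
            if atom in ("O", "OXT") and s == last_res[c]:
                q[i] -= 0.5
        return ChargeAssignment(charges=q, scheme="formal")
    table: dict[tuple[str, str], float] = {}
    for line in Path(scheme).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            res, atom, val = line.split()
            table[(res.upper(), atom.upper())] = float(val)
    missing = 0
    for i in range(n):
        key = (structure.res_names[i].upper(), structure.atom_names[i].upper())
        if key in table:
            q[i] = table[key]
        else:
            missing += 1
    if missing:
        warnings.warn(f"{missing} atoms absent from charge table; charge 0")
    return ChargeAssignment(charges=q, scheme=str(scheme))


# ------------------------------------------------------------------ grid

@dataclass
class PBGrid:
    """A uniform finite-difference grid with electrostatic metadata."""

    origin: np.ndarray  # Å, position of node (0, 0, 0)
    spacing: float  # Å, cubic voxels
    dims: tuple[int, int, int]
    potential: np.ndarray | None = None  # kT/e, shape dims
    eps_faces: tuple | None = None  # face dielectric along x, y, z
    kappa2: np.ndarray | None = None  # modified screening, Å^-2
    meta: dict = field(default_factory=dict)

    def node_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear potential at Cartesian points (NaN outside grid)."""
        if self.potential is None:
            raise ValueError("grid has no solved potential")
        pts = np.asarray(points, dtype=float)
        frac = (pts - self.origin) / self.spacing
        out = np.full(len(pts), np.nan)
        ok = np.all((frac >= 0) & (frac <= np.array(self.dims) - 1), axis=1)
        if ok.any():
            out[ok] = ndimage.map_coordinates(
                self.potential, frac[ok].T, order=1, mode="nearest"
            )
        return out


def build_grid(
    structure: Structure,
    padding: float = 20.0,
    n_longest: int = 123,
) -> PBGrid:
    """Grid geometry: cubic voxels covering the padded bounding box.

    The spacing is set so the longest padded box edge spans exactly
    ``n_longest`` nodes; the other dimensions get as many nodes as
    needed to cover their padded edges at the same spacing.
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    if n_longest < 33 or n_longest % 2 == 0:
        raise ValueError("n_longest must be odd and >= 33")
    lo = structure.coords.min(axis=0) - structure.radii.max()
    hi = structure.coords.max(axis=0) + structure.radii.max()
    edges = np.maximum(hi - lo, 1.0)  # degenerate molecules: 1 Å minimum
    centre = (lo + hi) / 2.0
    spacing = float((edges.max() + 2.0 * padding) / (n_longest - 1))
    dims = tuple(
        int(np.ceil((edges[k] + 2.0 * padding) / spacing - 1e-9)) + 1
        for k in range(3)
    )
    origin = centre - spacing * (np.array(dims) - 1) / 2.0
    return PBGrid(origin=origin, spacing=spacing, dims=dims)


def _inside_mask(grid: PBGrid, structure: Structure, inflate: float,
                 offset: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Nodes (of a possibly face-offset lattice) inside any atom sphere."""
    mask = np.zeros(dims, dtype=bool)
    h = grid.spacing
    base = grid.origin + offset
    for i in range(len(structure)):
        r = structure.radii[i] + inflate
        c = structure.coords[i]
        lo_idx = np.maximum(np.ceil((c - r - base) / h).astype(int), 0)
        hi_idx = np.minimum(np.floor((c + r - base) / h).astype(int),
                            np.array(dims) - 1)
        if (lo_idx > hi_idx).any():
            continue
        ax = [base[k] + h * np.arange(lo_idx[k], hi_idx[k] + 1) - c[k]
              for k in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = mask[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
                   lo_idx[2]:hi_idx[2] + 1]
        sub |= d2 <= r * r
    return mask


def _spread_charges(grid: PBGrid, structure: Structure,
                    charges: np.ndarray) -> np.ndarray:
    """Trilinear assignment of point charges to grid nodes."""
    rho = np.zeros(grid.dims)
    frac = (structure.coords - grid.origin) / grid.spacing
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    for a in range(len(structure)):
        if charges[a] == 0.0:
            continue
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[a, 0] if dx else 1 - t[a, 0])
                         * (t[a, 1] if dy else 1 - t[a, 1])
                         * (t[a, 2] if dz else 1 - t[a, 2]))
                    ix, iy, iz = i0[a] + np.array([dx, dy, dz])
                    if (0 <= ix < grid.dims[0] and 0 <= iy < grid.dims[1]
                            and 0 <= iz < grid.dims[2]):
                        rho[ix, iy, iz] += w * charges[a]
    return rho


def _boundary_potential(grid: PBGrid, structure: Structure,
                        charges: np.ndarray, eps_solvent: float,
                        kappa: float) -> np.ndarray:
    """Debye-Hückel single-sphere potential on the six grid faces."""
    phi = np.zeros(grid.dims)
    xs = grid.node_coords(0)
    ys = grid.node_coords(1)
    zs = grid.node_coords(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    face = np.zeros(grid.dims, dtype=bool)
    face[0, :, :] = face[-1, :, :] = True
    face[:, 0, :] = face[:, -1, :] = True
    face[:, :, 0] = face[:, :, -1] = True
    pts = np.column_stack([X[face], Y[face], Z[face]])
    vals = np.zeros(len(pts))
    for a in np.flatnonzero(charges != 0.0):
        d = np.linalg.norm(pts - structure.coords[a], axis=1)
        d = np.maximum(d, 1e-6)
        rad = structure.radii[a]
        screen = np.exp(-kappa * np.maximum(d - rad, 0.0)) / (1.0 + kappa * rad)
        vals += COULOMB_KT * charges[a] * screen / (eps_solvent * d)
    phi[face] = vals
    return phi


def solve_pb(
    grid: PBGrid,
    structure: Structure,
    charges: ChargeAssignment,
    eps_solute: float = 2.0,
    eps_solvent: float = 80.0,
    ionic_strength: float = 0.145,
    mode: str = "nonlinear",
    tol: float = 1e-4,
    probe: float = 1.4,
    max_iter: int = 20000,
    omega: float | None = None,
) -> PBGrid:
    """Relax the PB equation on the grid; returns the grid with potential.

    ``mode`` is ``"linear"`` (Debye-Hückel linearization) or
    ``"nonlinear"`` (full sinh term, Newton-linearized each sweep).
    Convergence is declared when the largest potential update in a
    sweep falls below ``tol`` (kT/e); non-convergence raises with the
    residual history attached.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if mode not in ("linear", "nonlinear"):
        raise ValueError(f"unknown mode {mode!r}")
    h = grid.spacing
    nx, ny, nz = grid.dims

    # face dielectrics from midpoint membership of the inflated solute
    eps = []
    for axis in range(3):
        dims = tuple(d - 1 if k == axis else d for k, d in enumerate(grid.dims))
        offset = np.zeros(3)
        offset[axis] = h / 2.0
        inside = _inside_mask(grid, structure, probe, offset, dims)
        eps.append(np.where(inside, eps_solute, eps_solvent))
    node_inside = _inside_mask(grid, structure, probe, np.zeros(3), grid.dims)
    kap2_val = KAPPA2_PER_MOLAR * ionic_strength
    kappa2 = np.where(node_inside, 0.0, kap2_val)
    kappa_solv = np.sqrt(kap2_val / eps_solvent) if kap2_val > 0 else 0.0

    b = 4.0 * np.pi * COULOMB_KT * _spread_charges(grid, structure,
                                                   charges.charges) / h
    phi = _boundary_potential(grid, structure, charges.charges,
                              eps_solvent, kappa_solv)

    if omega is None:
        omega = 2.0 / (1.0 + np.sin(np.pi / max(grid.dims)))
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    parity = (ii + jj + kk) % 2
    interior = np.zeros(grid.dims, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    colors = [interior & (parity == 0), interior & (parity == 1)]

    exm = np.zeros(grid.dims); exp_ = np.zeros(grid.dims)
    exm[1:, :, :] = eps[0]; exp_[:-1, :, :] = eps[0]
    eym = np.zeros(grid.dims); eyp = np.zeros(grid.dims)
    eym[:, 1:, :] = eps[1]; eyp[:, :-1, :] = eps[1]
    ezm = np.zeros(grid.dims); ezp = np.zeros(grid.dims)
    ezm[:, :, 1:] = eps[2]; ezp[:, :, :-1] = eps[2]
    eps_sum = exm + exp_ + eym + eyp + ezm + ezp
    kh2 = kappa2 * h * h

    history: list[float] = []
    for it in range(max_iter):
        max_delta = 0.0
        for mask in colors:
            nb = np.zeros(grid.dims)
            nb[1:-1, :, :] += exm[1:-1, :, :] * phi[:-2, :, :]
            nb[1:-1, :, :] += exp_[1:-1, :, :] * phi[2:, :, :]
            nb[:, 1:-1, :] += eym[:, 1:-1, :] * phi[:, :-2, :]
            nb[:, 1:-1, :] += eyp[:, 1:-1, :] * phi[:, 2:, :]
            nb[:, :, 1:-1] += ezm[:, :, 1:-1] * phi[:, :, :-2]
            nb[:, :, 1:-1] += ezp[:, :, 1:-1] * phi[:, :, 2:]
            if mode == "linear" or kap2_val == 0.0:
                denom = eps_sum + kh2
                new = (nb + b) / np.where(denom > 0, denom, 1.0)
            else:
                p = np.clip(phi, -30.0, 30.0)
                denom = eps_sum + kh2 * np.cosh(p)
                new = (nb + b - kh2 * (np.sinh(p) - p * np.cosh(p))) / np.where(
                    denom > 0, denom, 1.0)
            upd = phi + omega * (new - phi)
            delta = np.abs(upd - phi)[mask].max() if mask.any() else 0.0
            max_delta = max(max_delta, float(delta))
            phi[mask] = upd[mask]
        history.append(max_delta)
        if max_delta < tol:
            break
    else:
        err = RuntimeError(
            f"PB solver did not converge in {max_iter} iterations "
            f"(last residual {history[-1]:.3g} kT/e)"
        )
        err.residual_history = history  # type: ignore[attr-defined]
        raise err

    grid.potential = phi
    grid.eps_faces = tuple(eps)
    grid.kappa2 = kappa2
    grid.meta.update(
        mode=mode, iterations=len(history), eps_solute=eps_solute,
        eps_solvent=eps_solvent, ionic_strength=ionic_strength,
        temperature=TEMPERATURE, residual_history=history,
    )
    return grid


# ------------------------------------------------------------- surfaces

def surface_potential(
    structure: Structure,
    grid: PBGrid,
    probe: float = 1.4,
    n_points: int = 64,
    clamp: float = POTENTIAL_CLAMP,
) -> "pd.DataFrame":
    """Mean potential sampled on each atom's solvent-accessible sphere.

    Potentials are trilinearly interpolated at points on the
    probe-expanded sphere of every atom; sample points outside the grid
    are excluded with a warning.  The returned table carries both the
    raw mean and the value clamped to ±``clamp`` kT/e (the conventional
    colouring range for surface renderings).
    """
    import pandas as pd

    from .contacts import fibonacci_sphere

    unit = fibonacci_sphere(n_points)
    rows = []
    outside = 0
    for i in range(len(structure)):
        pts = structure.coords[i] + (structure.radii[i] + probe) * unit
        vals = grid.interpolate(pts)
        bad = ~np.isfinite(vals)
        outside += int(bad.sum())
        vals = vals[~bad]
        mean = float(vals.mean()) if len(vals) else np.nan
        rows.append({
            "atom_index": i,
            "atom_name": structure.atom_names[i],
            "chain": structure.chain_ids[i],
            "res_seq": int(structure.res_seq[i]),
            "res_name": structure.res_names[i],
            "mean_potential": mean,
            "clamped_potential": float(np.clip(mean, -clamp, clamp)),
        })
    if outside:
        warnings.warn(f"{outside} sample points fell outside the grid")
    return pd.DataFrame(rows)


def write_dx(grid: PBGrid) -> str:
    """Render the solved grid in OpenDX scalar-field format."""
    if grid.potential is None:
        raise ValueError("grid has no solved potential")
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    h = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6e} {oy:.6e} {oz:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.potential.ravel(order="C")
    for start in range(0, len(flat), 3):
        chunk = flat[start:start + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    return "\n".join(lines) + "\n"
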