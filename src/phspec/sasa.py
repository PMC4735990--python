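"""Lee-Richards solvent-accessible surface areas.

Each atom sphere is expanded by the probe radius (1.4 Å for water) and
cut into parallel slices; on every slice the exposed arc length of the
atom's circle, against the circles of all intersecting neighbours, is
measured exactly and integrated as arc x slice spacing.  The result is
deterministic for fixed inputs and converges to the analytic surface
as the slice spacing shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .properties import sliding_window_mean
from .structure import Structure

TWO_PI = 2.0 * np.pi


def load_reference_areas() -> dict[str, float]:
    """Residue -> maximal SASA (Å², extended Gly-X-Gly reference)."""
    text = resources.files("phspec").joinpath("data", "max_sasa.tsv").read_text()
    out = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            res, area = line.split()
            out[res.upper()] = float(area)
    return out


def _blocked_fraction(starts: np.ndarray, ends: np.ndarray) -> float:
    """Fraction of the circle covered by the union of arcs [start, end].

    Arcs are given in radians and may wrap; handled by splitting at 0.
    """
    if len(starts) == 0:
        return 0.0
    s = np.mod(starts, TWO_PI)
    e = s + (ends - starts)  # preserve arc widths
    segs = []
    for a, b in zip(s, e):
        if b <= TWO_PI:
            segs.append((a, b))
        else:  # wraps past 2*pi
            segs.append((a, TWO_PI))
            segs.append((0.0, b - TWO_PI))
    segs.sort()
    covered = 0.0
    cur_a, cur_b = segs[0]
    for a, b in segs[1:]:
        if a > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    covered += cur_b - cur_a
    return min(covered / TWO_PI, 1.0)


def lee_richards_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    slice_spacing: float = 0.1,
) -> np.ndarray:
    """Per-atom accessible areas (Å²) by the slicing algorithm."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if slice_spacing <= 0:
        raise ValueError("slice spacing must be > 0")
    n = len(radii)
    rexp = radii + probe
    areas = np.zeros(n)
    if n == 0:
        return areas
    tree = cKDTree(coords)
    rmax = rexp.max()
    for i in range(n):
        ri = rexp[i]
        nbrs = [j for j in tree.query_ball_point(coords[i], ri + rmax)
                if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + rexp[j]]
        zi = coords[i, 2]
        nz = max(int(np.ceil(2.0 * ri / slice_spacing)), 1)
        # slice midplanes through the sphere
        zs = zi - ri + (np.arange(nz) + 0.5) * slice_spacing
        zs = zs[np.abs(zs - zi) < ri]
        if len(nbrs) == 0:
            # whole zone of each slice exposed: sum(2*pi*R*dz) over slices
            areas[i] = TWO_PI * ri * slice_spacing * len(zs)
            continue
        ncoords = coords[nbrs]
        nrexp = rexp[np.array(nbrs)]
        dxy = ncoords[:, :2] - coords[i, :2]
        d2d = np.hypot(dxy[:, 0], dxy[:, 1])
        beta = np.arctan2(dxy[:, 1], dxy[:, 0])
        atom_area = 0.0
        for z in zs:
            riz = np.sqrt(max(ri * ri - (z - zi) ** 2, 0.0))
            dz_n = z - ncoords[:, 2]
            act = np.abs(dz_n) < nrexp
            if not act.any():
                atom_area += TWO_PI * ri * slice_spacing
                continue
            rjz = np.sqrt(nrexp[act] ** 2 - dz_n[act] ** 2)
            d = d2d[act]
            bet = beta[act]
            if riz <= 0.0:
                # degenerate point circle: exposed unless inside a neighbour
                if not (d < rjz).any():
                    atom_area += 0.0
                continue
            # fully covered by one neighbour circle?
            if (d + riz <= rjz).any():
                continue
            cuts = (d < riz + rjz) & (d + rjz > riz) & (d > 1e-12)
            if not cuts.any():
                atom_area += TWO_PI * ri * slice_spacing
                continue
            dc, rc, bc = d[cuts], rjz[cuts], bet[cuts]
            cosa = (dc * dc + riz * riz - rc * rc) / (2.0 * dc * riz)
            alpha = np.arccos(np.clip(cosa, -1.0, 1.0))
            frac = _blocked_fraction(bc - alpha, bc + alpha)
            atom_area += (1.0 - frac) * TWO_PI * ri * slice_spacing
        areas[i] = atom_area
    return areas


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible areas for one structure."""

    atom_keys: list[tuple]  # (chain, res_seq, res_name, atom_name)
    per_atom_area: np.ndarray
    residue_keys: list[tuple]  # (chain, res_seq, res_name)
    per_residue_area: np.ndarray
    probe_radius: float
    slice_spacing: float

    def total(self) -> float:
        return float(self.per_atom_area.sum())


def deduplicate(structure: Structure) -> Structure:
    """Drop atoms with coincident centres and identical radii."""
    seen = {}
    keep = np.ones(len(structure), dtype=bool)
    for i in range(len(structure)):
        key = (tuple(np.round(structure.coords[i], 6)), round(structure.radii[i], 6))
        if key in seen:
            keep[i] = False
            warnings.warn(
                f"duplicate atom {structure.atom_names[i]} at "
                f"{structure.coords[i]}: removed"
            )
        else:
            seen[key] = i
    return structure.subset(keep) if not keep.all() else structure


def lee_richards_sasa(
    structure: Structure,
    probe: float = 1.4,
    slice_spacing: float = 0.1,
) -> SasaResult:
    """SASA of a structure (Å²), per atom and summed per residue."""
    structure = deduplicate(structure)
    per_atom = lee_richards_areas(
        structure.coords, structure.radii, probe, slice_spacing
    )
    res_keys = structure.residue_keys()
    res_idx = structure.residue_index()
    per_res = np.zeros(len(res_keys))
    np.add.at(per_res, res_idx, per_atom)
    atom_keys = [
        (c, int(s), rn, an)
        for c, s, rn, an in zip(
            structure.chain_ids, structure.res_seq,
            structure.res_names, structure.atom_names,
        )
    ]
    return SasaResult(
        atom_keys=atom_keys,
        per_atom_area=per_atom,
        residue_keys=res_keys,
        per_residue_area=per_res,
        probe_radius=probe,
        slice_spacing=slice_spacing,
    )


@dataclass
class ExposureProfile:
    """Per-residue solvent-exposure fractions with window smoothing."""

    residue_keys: list[tuple]
    fractions: np.ndarray  # raw, clipped to [0, 1]; NaN where undefined
    smoothed: np.ndarray
    window: int
    undefined: np.ndarray  # bool mask of residues lacking a reference area


def _nan_window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Window mean ignoring NaN cells (mean over defined positions)."""
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    s = sliding_window_mean(filled, window)
    c = sliding_window_mean(mask.astype(float), window)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c > 0, s / c, np.nan)
    return out


def exposure_fractions(
    sasa: SasaResult,
    reference: dict[str, float] | None = None,
    window: int = 9,
) -> ExposureProfile:
    """Fraction of each residue's reference area that is solvent exposed.

    fraction = per-residue SASA / reference maximal area, clipped to
    [0, 1].  Residues without a reference entry get NaN, are flagged,
    and are excluded from smoothing.
    """
    if reference is None:
        reference = load_reference_areas()
    fracs = np.full(len(sasa.residue_keys), np.nan)
    undef = np.zeros(len(sasa.residue_keys), dtype=bool)
    for i, (_, _, res_name) in enumerate(sasa.residue_keys):
        ref = reference.get(res_name.upper())
        if ref is None:
            undef[i] = True
            warnings.warn(f"no reference area for residue {res_name!r}")
        else:
            fracs[i] = min(max(sasa.per_residue_area[i] / ref, 0.0), 1.0)
    n = len(fracs)
    eff_window = min(window, n if n % 2 == 1 else n - 1)
    return ExposureProfile(
        residue_keys=list(sasa.residue_keys),
        fractions=fracs,
        smoothed=_nan_window_mean(fracs, max(eff_window, 1)),
        window=window,
        undefined=undef,
    )


@dataclass
class DeltaSasa:
    """Per-residue area buried upon complexation (apo minus complex)."""

    residue_keys: list[tuple]
    buried: np.ndarray  # Å², floored at 0
    flag_threshold: float
    binding_site: np.ndarray  # bool, buried > threshold


def delta_sasa(
    apo: SasaResult,
    complexed: SasaResult,
    flag_threshold: float = 1.0,
) -> DeltaSasa:
    """Residue-level burial between an apo and a complexed SASA result.

    The complexed result may contain extra (ligand) atoms, but every
    apo protein atom must be present in it; residues burying more than
    ``flag_threshold`` Å² are flagged as binding-site residues.
    """
    comp_atom = dict(zip(complexed.atom_keys, complexed.per_atom_area))
    orphans = [k for k in apo.atom_keys if k not in comp_atom]
    if orphans:
        raise ValueError(f"atoms missing from complex: {orphans[:5]}"
                         f"{'...' if len(orphans) > 5 else ''}")
    res_index = {k: i for i, k in enumerate(apo.residue_keys)}
    buried = np.zeros(len(apo.residue_keys))
    for key, apo_area in zip(apo.atom_keys, apo.per_atom_area):
        ri = res_index[key[:3]]
        buried[ri] += apo_area - comp_atom[key]
    buried = np.maximum(buried, 0.0)
    return DeltaSasa(
        residue_keys=list(apo.residue_keys),
        buried=buried,
        flag_threshold=flag_threshold,
        binding_site=buried > flag_threshold,
    )
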