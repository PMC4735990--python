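"""Ligand-protein contact complementarity.

Partitions the surface a ligand group buries against the protein into
legitimate (chemically compatible) and illegitimate contacts, following
the contact-analysis idea of Sobolev et al. (LIGIN): every atom carries
a hydropathy class (hydrophilic donor / acceptor / donor-acceptor,
hydrophobic, neutral), buried surface is attributed to the nearest
protein atom, and a class-pair table decides compatibility.  The key
chemical constraint is that hydrophilic-hydrophobic contacts are always
illegitimate.

The headline statistics per ligand group (e.g. one phosphate of an
inositol phosphate) are the complementarity C = S_legit - S_illegit and
its normalization NC = C / reference area, where the reference is the
group's accessible surface on the isolated ligand.

Buried surface is measured on a deterministic spherical point lattice
on each ligand atom's probe-expanded sphere, so that the attributed
area and the isolated-minus-complexed SASA difference agree to
floating-point precision by construction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import Structure

CLASSES = ("donor", "acceptor", "donor_acceptor", "hydrophobic", "neutral")
HYDROPHILIC = {"donor", "acceptor", "donor_acceptor"}

P_O_BOND = 1.8  # Å, phosphorus-oxygen bond distance cutoff
C_O_BOND = 1.6  # Å, carbon-oxygen bond distance cutoff


# ---------------------------------------------------------------- tables

def load_atom_class_table(path: str | Path | None = None) -> dict:
    """(residue, atom) -> class; residue '*' matches any (backbone)."""
    if path is None:
        text = resources.files("phspec").joinpath(
            "data", "atom_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        res, atom, cls = line.split()
        if cls not in CLASSES:
            raise ValueError(f"unknown atom class {cls!r}")
        table[(res.upper(), atom.upper())] = cls
    return table


def load_legitimacy_table(path: str | Path | None = None) -> dict:
    """(class, class) -> bool legitimacy matrix, symmetrized.

    Any table must keep hydrophilic-hydrophobic pairs illegitimate;
    violating edits are rejected.
    """
    if path is None:
        text = resources.files("phspec").joinpath(
            "data", "legitimacy.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows = [ln.split("#", 1)[0].rstrip() for ln in text.splitlines()]
    rows = [ln for ln in rows if ln.strip()]
    header = rows[0].split()
    mat = {}
    for ln in rows[1:]:
        fields = ln.split()
        rc = fields[0]
        for cc, v in zip(header, fields[1:]):
            mat[(rc, cc)] = bool(int(v))
    for a in CLASSES:
        for b in CLASSES:
            if mat[(a, b)] != mat[(b, a)]:
                raise ValueError(f"legitimacy table asymmetric at ({a}, {b})")
    for h in HYDROPHILIC:
        if mat[(h, "hydrophobic")]:
            raise ValueError(
                "legitimacy table marks a hydrophilic-hydrophobic pair "
                "legitimate; such contacts must stay illegitimate"
            )
    return mat


# ------------------------------------------------------------- classing

def classify_atoms(
    structure: Structure,
    table: dict | None = None,
) -> list[str]:
    """Assign one hydropathy class to every atom.

    Protein atoms use the packaged (residue, atom) table with a
    backbone wildcard; unmatched atoms fall back to neutral with a
    warning.  Hetero (ligand) atoms are classed by element and local
    connectivity: phosphate/ester oxygens (bonded to P) are acceptors,
    hydroxyl oxygens (bonded to C only) are donor-acceptors, carbons
    are hydrophobic, nitrogens donors, phosphorus neutral.
    """
    if table is None:
        table = load_atom_class_table()
    classes: list[str] = []
    het_idx = np.flatnonzero(structure.is_hetero)
    het_coords = structure.coords[het_idx] if len(het_idx) else None
    for i in range(len(structure)):
        if structure.is_hetero[i]:
            classes.append(_ligand_class(structure, i, het_idx, het_coords))
            continue
        key = (structure.res_names[i].upper(), structure.atom_names[i].upper())
        cls = table.get(key) or table.get(("*", key[1]))
        if cls is None:
            warnings.warn(f"no class for atom {key}; using neutral")
            cls = "neutral"
        classes.append(cls)
    return classes


def _ligand_class(structure, i, het_idx, het_coords) -> str:
    el = structure.elements[i].upper()
    if el == "P":
        return "neutral"
    if el == "C":
        return "hydrophobic"
    if el == "N":
        return "donor"
    if el == "S":
        return "donor_acceptor"
    if el == "O":
        d = np.linalg.norm(het_coords - structure.coords[i], axis=1)
        for j, dist in zip(het_idx, d):
            if j != i and structure.elements[j].upper() == "P" and dist <= P_O_BOND:
                return "acceptor"
        for j, dist in zip(het_idx, d):
            if j != i and structure.elements[j].upper() == "C" and dist <= C_O_BOND:
                return "donor_acceptor"
        return "acceptor"
    return "neutral"


# ---------------------------------------------------------------- groups

@dataclass
class LigandGroup:
    """A labelled chemical group of ligand atoms (absolute indices)."""

    label: str
    atom_indices: np.ndarray

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)


def define_phosphate_groups(
    complex_structure: Structure,
    ligand_mask: np.ndarray,
    label_map: dict[int, str] | None = None,
) -> list[LigandGroup]:
    """Group each ligand phosphorus with its bonded oxygens.

    Oxygens within the P-O bond cutoff (1.8 Å) join the nearest
    phosphorus; ester oxygens bonded to both C and P belong to the
    phosphate.  Labels come from the phosphorus atom name digits (P1,
    P3, ...) with an optional override map keyed by phosphorus atom
    index.  A phosphate with fewer than 3 bonded oxygens is kept, with
    a warning.
    """
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    lig_idx = np.flatnonzero(ligand_mask)
    p_idx = [i for i in lig_idx if complex_structure.elements[i].upper() == "P"]
    if not p_idx:
        return []
    groups = []
    o_idx = [i for i in lig_idx if complex_structure.elements[i].upper() == "O"]
    owner: dict[int, int] = {}
    for oi in o_idx:
        dists = [np.linalg.norm(complex_structure.coords[oi]
                                - complex_structure.coords[pi]) for pi in p_idx]
        best = int(np.argmin(dists))
        if dists[best] <= P_O_BOND:
            owner[oi] = p_idx[best]
    for seq, pi in enumerate(p_idx, start=1):
        members = [pi] + [oi for oi, pj in owner.items() if pj == pi]
        if len(members) - 1 < 3:
            warnings.warn(
                f"phosphate {complex_structure.atom_names[pi]} has only "
                f"{len(members) - 1} bonded oxygens"
            )
        if label_map and pi in label_map:
            label = label_map[pi]
        else:
            m = re.search(r"(\d+)", complex_structure.atom_names[pi])
            label = f"P{m.group(1)}" if m else f"P{seq}"
        groups.append(LigandGroup(label=label, atom_indices=np.array(members)))
    return groups


# ----------------------------------------------------- contact surfaces

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class GroupContact:
    """Contact statistics of one ligand group."""

    label: str
    s_legit: float
    s_illegit: float
    buried_area: float
    reference_area: float  # group SASA on the isolated ligand

    @property
    def complementarity(self) -> float:
        return self.s_legit - self.s_illegit

    @property
    def normalized_complementarity(self) -> float:
        return normalized_complementarity(self.complementarity,
                                          self.reference_area)


def complementarity(s_legit: float, s_illegit: float) -> float:
    """C = legitimate minus illegitimate contact surface area (Å²)."""
    if s_legit < 0 or s_illegit < 0:
        raise ValueError("contact surface areas must be >= 0")
    return s_legit - s_illegit


def normalized_complementarity(c: float, reference_area: float) -> float:
    """NC = C / reference area (dimensionless)."""
    if reference_area <= 0:
        raise ValueError("reference area must be > 0")
    return c / reference_area


def contact_surfaces(
    group: LigandGroup,
    complex_structure: Structure,
    ligand_mask: np.ndarray,
    classes: list[str] | None = None,
    probe: float = 1.4,
    n_points: int = 4096,
    legitimacy: dict | None = None,
) -> GroupContact:
    """Legitimate/illegitimate contact surface of one ligand group.

    For every group atom, points on its probe-expanded sphere that are
    accessible on the isolated ligand but occluded by the protein are
    buried contact surface; each buried point is attributed to the
    protein atom whose expanded surface is nearest and counted as
    legitimate or illegitimate according to the class-pair table.  The
    attributed area equals the group's isolated-minus-complexed SASA
    difference exactly (same point sets on both sides).
    """
    if classes is None:
        classes = classify_atoms(complex_structure)
    if legitimacy is None:
        legitimacy = load_legitimacy_table()
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    prot_idx = np.flatnonzero(~ligand_mask)
    lig_idx = np.flatnonzero(ligand_mask)
    coords = complex_structure.coords
    rexp = complex_structure.radii + probe
    unit = fibonacci_sphere(n_points)

    s_legit = s_illegit = buried_area = reference_area = 0.0
    for ai in group.atom_indices:
        ra = rexp[ai]
        pts = coords[ai] + ra * unit
        area_per_pt = 4.0 * np.pi * ra * ra / n_points
        # occlusion by the rest of the ligand (isolated-ligand surface)
        acc_iso = np.ones(n_points, dtype=bool)
        for j in lig_idx:
            if j == ai:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            acc_iso &= d2 >= rexp[j] ** 2
        reference_area += acc_iso.sum() * area_per_pt
        if len(prot_idx) == 0 or not acc_iso.any():
            continue
        # only protein atoms whose expanded sphere can reach this sphere;
        # any buried point's nearest owner (negative surface distance) is
        # necessarily among them
        ctr_d = np.linalg.norm(coords[prot_idx] - coords[ai], axis=1)
        near = prot_idx[ctr_d < ra + rexp[prot_idx]]
        if len(near) == 0:
            continue
        # protein occlusion of the isolated-accessible points
        cand = np.flatnonzero(acc_iso)
        pp = pts[cand]
        dprot = np.linalg.norm(
            pp[:, None, :] - coords[near][None, :, :], axis=2
        )
        inside = dprot < rexp[near][None, :]
        buried_pts = inside.any(axis=1)
        if not buried_pts.any():
            continue
        buried_area += buried_pts.sum() * area_per_pt
        # nearest protein atom by expanded-surface distance
        surf_dist = dprot[buried_pts] - rexp[near][None, :]
        owners = near[np.argmin(surf_dist, axis=1)]
        lig_cls = classes[ai]
        for po in owners:
            if legitimacy[(lig_cls, classes[po])]:
                s_legit += area_per_pt
            else:
                s_illegit += area_per_pt
    return GroupContact(
        label=group.label,
        s_legit=s_legit,
        s_illegit=s_illegit,
        buried_area=buried_area,
        reference_area=reference_area,
    )


@dataclass
class ContactReport:
    """Per-group contact statistics for one complex."""

    complex_id: str
    groups: list[GroupContact] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            nc = np.nan
            if g.reference_area > 0:
                nc = g.normalized_complementarity
            else:
                warnings.warn(f"group {g.label}: zero reference area, NC undefined")
            rows.append({
                "complex_id": self.complex_id,
                "group": g.label,
                "S_legit": g.s_legit,
                "S_illegit": g.s_illegit,
                "C": g.complementarity,
                "NC": nc,
                "reference_area": g.reference_area,
            })
        return pd.DataFrame(rows)


def analyze_complex(
    complex_structure: Structure,
    ligand_resnames: list[str],
    complex_id: str = "",
    probe: float = 1.4,
    n_points: int = 4096,
) -> ContactReport:
    """Full contact analysis of one protein-ligand complex."""
    names = {r.upper() for r in ligand_resnames}
    ligand_mask = np.array(
        [h and rn.upper() in names
         for h, rn in zip(complex_structure.is_hetero, complex_structure.res_names)]
    )
    if not ligand_mask.any():
        raise ValueError(f"no ligand atoms with residue name(s) {sorted(names)}")
    classes = classify_atoms(complex_structure)
    groups = define_phosphate_groups(complex_structure, ligand_mask)
    report = ContactReport(complex_id=complex_id)
    for g in groups:
        report.groups.append(
            contact_surfaces(
                g, complex_structure, ligand_mask,
                classes=classes, probe=probe, n_points=n_points,
            )
        )
    return report
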