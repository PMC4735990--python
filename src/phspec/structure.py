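"""PDB structure handling.

Parses PDB text with gemmi into a flat, numpy-friendly atom table with
van der Waals radii assigned by element.  One model is kept per
structure (NMR ensembles default to the first model, matching common
practice when no average structure is deposited); alternate locations
are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

_FALLBACK_RADIUS = 1.70


def load_vdw_radii() -> dict[str, float]:
    """Element -> van der Waals radius (Å) from the packaged table."""
    text = resources.files("phspec").joinpath("data", "vdw_radii.tsv").read_text()
    radii = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            el, r = line.split()
            radii[el.upper()] = float(r)
    return radii


@dataclass
class Structure:
    """A flat atom table for one model of a structure.

    All arrays are parallel over atoms.  ``is_hetero`` marks HETATM
    records (ligands, ions); waters are excluded at read time.
    """

    atom_names: list[str]
    elements: list[str]
    res_names: list[str]
    res_seq: np.ndarray  # int, author numbering passed through verbatim
    chain_ids: list[str]
    coords: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # Å
    occupancies: np.ndarray
    is_hetero: np.ndarray  # bool
    model_id: int = 1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.is_hetero = np.asarray(self.is_hetero, dtype=bool)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if (self.radii <= 0).any():
            raise ValueError("non-positive van der Waals radius")

    def __len__(self) -> int:
        return len(self.atom_names)

    # ---- selections -------------------------------------------------

    def subset(self, mask: np.ndarray) -> "Structure":
        idx = np.flatnonzero(np.asarray(mask))
        return Structure(
            atom_names=[self.atom_names[i] for i in idx],
            elements=[self.elements[i] for i in idx],
            res_names=[self.res_names[i] for i in idx],
            res_seq=self.res_seq[idx],
            chain_ids=[self.chain_ids[i] for i in idx],
            coords=self.coords[idx],
            radii=self.radii[idx],
            occupancies=self.occupancies[idx],
            is_hetero=self.is_hetero[idx],
            model_id=self.model_id,
        )

    def protein(self) -> "Structure":
        return self.subset(~self.is_hetero)

    def ligand(self, resnames: set[str] | list[str]) -> "Structure":
        names = {r.upper() for r in resnames}
        mask = np.array([r.upper() in names for r in self.res_names])
        return self.subset(mask)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, res_seq, res_name) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, s, n in zip(self.chain_ids, self.res_seq, self.res_names):
            seen.setdefault((c, int(s), n), None)
        return list(seen)

    def residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys` order."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array(
            [keys[(c, int(s), n)]
             for c, s, n in zip(self.chain_ids, self.res_seq, self.res_names)],
            dtype=int,
        )


def read_structure(
    pdb_source: str | Path,
    model_policy: int | str = "first",
    keep_water: bool = False,
) -> Structure:
    """Read one model from PDB-format text or a file path.

    ``model_policy`` selects the model: ``"first"`` (default, the rule
    used for NMR ensembles without an average structure) or a 1-based
    model number.  Alternate locations are resolved to the
    highest-occupancy conformer (ties: first in file order).  Waters
    are dropped unless ``keep_water``; other HETATM atoms are retained
    and flagged.
    """
    if isinstance(pdb_source, Path) or (
        "\n" not in str(pdb_source) and Path(str(pdb_source)).exists()
    ):
        text = Path(pdb_source).read_text()
    else:
        text = str(pdb_source)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    if model_policy == "first":
        model = st[0]
    else:
        num = int(model_policy)
        matches = [m for m in st if m.num == num]
        if not matches:
            raise ValueError(f"model {num} not found")
        model = matches[0]

    radii_table = load_vdw_radii()
    names, elements, res_names, chains = [], [], [], []
    res_seq, coords, radii, occs, het = [], [], [], [], []
    # altloc resolution: best occupancy per (chain, resseq, resname, atom)
    best: dict[tuple, tuple[float, int]] = {}
    records = []
    for chain in model:
        for res in chain:
            for atom in res:
                records.append((chain.name, res, atom))
    for i, (cname, res, atom) in enumerate(records):
        key = (cname, res.seqid.num, res.name, atom.name)
        occ = float(atom.occ)
        if key not in best or occ > best[key][0]:
            best[key] = (occ, i)
    keep = {i for _, i in best.values()}
    for i, (cname, res, atom) in enumerate(records):
        if i not in keep:
            continue
        if not keep_water and res.name.strip().upper() in WATER_RESNAMES:
            continue
        el = atom.element.name.upper()
        if el not in radii_table:
            warnings.warn(
                f"unknown element {el!r} for atom {atom.name}; "
                f"using fallback radius {_FALLBACK_RADIUS} Å"
            )
            r = _FALLBACK_RADIUS
        else:
            r = radii_table[el]
        names.append(atom.name)
        elements.append(el)
        res_names.append(res.name.strip().upper())
        chains.append(cname)
        res_seq.append(res.seqid.num)
        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        radii.append(r)
        occs.append(float(atom.occ))
        het.append(res.het_flag == "H")
    if not names:
        raise ValueError("no ATOM/HETATM records in PDB input")
    return Structure(
        atom_names=names,
        elements=elements,
        res_names=res_names,
        res_seq=np.array(res_seq),
        chain_ids=chains,
        coords=np.array(coords),
        radii=np.array(radii),
        occupancies=np.array(occs),
        is_hetero=np.array(het),
        model_id=model.num,
    )


def write_pdb(structure: Structure) -> str:
    """Render a Structure as PDB-format text (fixed-width records)."""
    lines = []
    for i in range(len(structure)):
        rec = "HETATM" if structure.is_hetero[i] else "ATOM  "
        name = structure.atom_names[i]
        # PDB column convention: element right-aligned in cols 13-14
        pname = name if len(name) >= 4 else f" {name:<3s}"
        x, y, z = structure.coords[i]
        el = structure.elements[i]
        lines.append(
            f"{rec}{i + 1:5d} {pname:<4s} {structure.res_names[i]:<3s} "
            f"{structure.chain_ids[i]:1s}{int(structure.res_seq[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancies[i]:6.2f}"
            f"{0.0:6.2f}          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
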