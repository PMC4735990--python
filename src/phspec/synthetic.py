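"""Labelled synthetic PH-like sequences and toy complexes.

Real PH domains are scarce and their curated alignments are external
inputs, so every stage of the pipeline is exercised on synthetic cases
with planted, verifiable signal:

* sequence cases — ~110-residue sequences with a beta1/beta2-like loop
  window whose composition encodes one of the four binding-specificity
  groups (signature motif planted for groups 1 and 3 and rejected for
  groups 2 and 4; hydrophilic/basic vs hydrophobic loop composition);
* toy complexes — a protein-like atom cluster packed in a sphere plus
  a ligand bearing phosphate-like groups at controllable burial depths
  and pocket hydropathy classes, written as valid PDB text.

Background residues are uniform over the 20 amino acids (maximum
contrast control); an archetype strength ``effect`` in [0, 1] scales
both the motif-planting probability and the loop-composition rewrite
rate, so ``effect = 0`` is an exact negative control in which the four
groups are indistinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .motif import MotifPattern, default_patterns
from .properties import STANDARD_AMINO_ACIDS
from .structure import Structure

DEFAULT_LENGTH = 110
#: fixed half-open beta1/beta2-like loop window planted in every case
LOOP_WINDOW = (10, 28)

HYDROPHILIC_BASIC = "KRNS"  # groups 1 and 2 loop composition
HYDROPHOBIC_RUN = "ILVF"  # group 3 loop composition

_MAX_ATTEMPTS = 1000


@dataclass
class SyntheticCase:
    """One labelled synthetic sequence (optionally with a structure)."""

    case_id: str
    true_group: int
    sequence: str
    loop_window: tuple[int, int]
    params: dict = field(default_factory=dict)
    structure: Structure | None = None
    pdb_text: str | None = None


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # one independent stream per case, reproducible from (seed, index)
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(case_index)])


def _random_background(rng, length: int, pattern: MotifPattern) -> str:
    """Uniform background sequence with no accidental motif match."""
    letters = np.array(list(STANDARD_AMINO_ACIDS))
    for attempt in range(_MAX_ATTEMPTS):
        seq = "".join(rng.choice(letters, size=length))
        if not pattern.regex.search(seq):
            return seq
    warnings.warn("rejection sampling exhausted; reseeding background")
    return _random_background(
        np.random.default_rng(rng.integers(2**31)), length, pattern
    )


def _archetype_letter(rng, group: int, effect: float) -> str:
    pool = HYDROPHOBIC_RUN if group == 3 else HYDROPHILIC_BASIC
    if rng.random() < effect:
        return pool[rng.integers(len(pool))]
    return STANDARD_AMINO_ACIDS[rng.integers(20)]


def _motif_instance(rng, group: int, effect: float) -> str:
    """Sample a literal instance of the default signature pattern.

    Gap residues follow the group archetype, so the hydrophobic run of
    a Group-3 loop lives inside the motif gap.
    """
    gap_len = int(rng.integers(6, 10))  # keeps the instance inside the loop
    arch = lambda: _archetype_letter(rng, group, effect)  # noqa: E731
    parts = [
        "K", arch(), "SG"[rng.integers(2)],
        "".join(arch() for _ in range(gap_len)),
        "KR"[rng.integers(2)], arch(), "R",
    ]
    return "".join(parts)


def generate_sequence_case(
    group: int,
    length: int = DEFAULT_LENGTH,
    effect: float = 1.0,
    seed: int = 0,
    case_index: int = 0,
    pattern: MotifPattern | None = None,
) -> SyntheticCase:
    """Generate one labelled sequence with planted group signal.

    Groups 1 and 3 receive a literal motif instance inside the loop
    window (with probability ``effect``); groups 2 and 4 are
    rejection-verified to contain no match anywhere.  Loop positions
    outside the motif are rewritten to the group archetype at rate
    ``effect`` (groups 1, 2: K/R/N/S; group 3: I/L/V/F; group 4: left
    at background).
    """
    if group not in (1, 2, 3, 4):
        raise ValueError(f"group must be 1-4, got {group}")
    if length < 60:
        raise ValueError("length must be >= 60")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")
    if pattern is None:
        pattern = default_patterns()[0]
    rng = _case_rng(seed, case_index)
    lo, hi = LOOP_WINDOW
    seq = list(_random_background(rng, length, pattern))

    if group in (1, 3):
        plant_motif = rng.random() < effect
        # rewrite the loop to the archetype composition
        for i in range(lo, hi):
            seq[i] = _archetype_letter(rng, group, effect)
        if plant_motif:
            inst = _motif_instance(rng, group, effect)
            start = lo + int(rng.integers(0, hi - lo - len(inst) + 1))
            seq[start:start + len(inst)] = inst
    elif group == 2:
        for attempt in range(_MAX_ATTEMPTS):
            for i in range(lo, hi):
                seq[i] = _archetype_letter(rng, 2, effect)
            if not pattern.regex.search("".join(seq)):
                break
        else:
            warnings.warn("group-2 loop rejection exhausted; leaving last draw")
    # group 4: loop stays at background (already motif-free)

    return SyntheticCase(
        case_id=f"g{group}_s{seed}_i{case_index}",
        true_group=group,
        sequence="".join(seq),
        loop_window=LOOP_WINDOW,
        params={"seed": seed, "case_index": case_index,
                "effect": effect, "length": length},
    )


def generate_cases(
    n_per_group: int,
    effect: float = 1.0,
    seed: int = 1,
    groups: tuple[int, ...] = (1, 2, 3, 4),
    length: int = DEFAULT_LENGTH,
) -> list[SyntheticCase]:
    """A balanced batch of sequence cases, one RNG stream per case."""
    cases = []
    idx = 0
    for group in groups:
        for _ in range(n_per_group):
            cases.append(
                generate_sequence_case(
                    group, length=length, effect=effect,
                    seed=seed, case_index=idx,
                )
            )
            idx += 1
    return cases


# ------------------------------------------------------- toy complexes

#: atom identity used for each hydropathy class so that the packaged
#: (residue, atom) class table recognises toy atoms without warnings
_CLASS_ATOMS = {
    "donor": ("LYS", "NZ", "N"),
    "acceptor": ("ASP", "OD1", "O"),
    "donor_acceptor": ("SER", "OG", "O"),
    "hydrophobic": ("LEU", "CD1", "C"),
    "neutral": ("GLY", "C", "C"),
}

#: tetrahedral unit offsets for the four oxygens of a phosphate
_TETRA = np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)

P_O_LENGTH = 1.55  # Å


@dataclass
class ToyLigandSpec:
    """Placement of phosphate-like groups relative to the protein sphere.

    ``depths`` gives each group's burial depth in Å below the protein
    sphere surface (negative values push the group out into solvent);
    ``pocket_classes`` optionally forces the hydropathy class of
    protein atoms within ``pocket_radius`` of each group's phosphorus.
    """

    depths: list[float]
    pocket_classes: list[str | None] | None = None
    pocket_radius: float = 6.0
    spread_deg: float = 35.0


@dataclass
class ToyComplex:
    """A generated protein-cluster + ligand complex with ground truth."""

    structure: Structure
    pdb_text: str
    ligand_mask: np.ndarray
    group_depths: list[float]
    pocket_classes: list[str | None]
    params: dict


def generate_toy_complex(
    n_protein_atoms: int,
    ligand_spec: ToyLigandSpec,
    seed: int = 0,
    fraction_hydrophobic: float = 0.5,
    min_separation: float = 2.4,
) -> ToyComplex:
    """Pack a protein-like cluster and place a phosphate-bearing ligand.

    Protein atoms are rejection-sampled inside a sphere with a minimum
    inter-atom separation; each carries an explicit hydropathy class
    realised through a (residue, atom) identity the packaged class
    table recognises.  Phosphate groups (P + 4 O) sit at the requested
    burial depths along spread directions.  Output is deterministic
    for a fixed seed, and the PDB text round-trips through the reader.
    """
    if n_protein_atoms < 3:
        raise ValueError("need at least 3 protein atoms")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    m = len(ligand_spec.depths)
    pocket = list(ligand_spec.pocket_classes or [None] * m)
    if len(pocket) != m:
        raise ValueError("pocket_classes length must match depths")

    # ligand first: groups along directions fanned around +x in the xy plane
    sphere_r = max(6.0, (n_protein_atoms * min_separation**3 * 2.2) ** (1 / 3))
    lig_coords, lig_names, lig_elements = [], [], []
    angles = (np.arange(m) - (m - 1) / 2.0) * np.deg2rad(ligand_spec.spread_deg)
    for k, (depth, ang) in enumerate(zip(ligand_spec.depths, angles), start=1):
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        p_pos = (sphere_r - depth) * direction
        lig_coords.append(p_pos)
        lig_names.append(f"P{k}")
        lig_elements.append("P")
        for j, off in enumerate(_TETRA, start=1):
            lig_coords.append(p_pos + P_O_LENGTH * off)
            lig_names.append(f"O{k}{j}")
            lig_elements.append("O")
    lig_coords = np.array(lig_coords)

    # protein atoms: uniform in the sphere, clash-rejected
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_protein_atoms:
        attempts += 1
        if attempts > _MAX_ATTEMPTS * n_protein_atoms:
            raise RuntimeError("cannot satisfy clash constraints")
        u = rng.random()
        pos = sphere_r * u ** (1 / 3) * _random_unit(rng)
        if any(np.linalg.norm(pos - q) < min_separation for q in placed):
            continue
        if np.linalg.norm(lig_coords - pos, axis=1).min() < min_separation + 0.4:
            continue
        placed.append(pos)
    prot_coords = np.array(placed)

    classes = [
        "hydrophobic" if rng.random() < fraction_hydrophobic else
        ("donor" if rng.random() < 0.5 else "acceptor")
        for _ in range(n_protein_atoms)
    ]
    for k, cls in enumerate(pocket):
        if cls is None:
            continue
        p_pos = lig_coords[k * 5]
        near = np.linalg.norm(prot_coords - p_pos, axis=1) <= ligand_spec.pocket_radius
        for i in np.flatnonzero(near):
            classes[i] = cls

    from .structure import load_vdw_radii, write_pdb

    radii_table = load_vdw_radii()
    atom_names, elements, res_names, res_seq, coords, radii, het = \
        [], [], [], [], [], [], []
    for i, (pos, cls) in enumerate(zip(prot_coords, classes)):
        res, atom, el = _CLASS_ATOMS[cls]
        atom_names.append(atom)
        elements.append(el)
        res_names.append(res)
        res_seq.append(i + 1)
        coords.append(pos)
        radii.append(radii_table[el])
        het.append(False)
    for name, el, pos in zip(lig_names, lig_elements, lig_coords):
        atom_names.append(name)
        elements.append(el)
        res_names.append("IPX")  # synthetic inositol-phosphate-like ligand
        res_seq.append(n_protein_atoms + 1)
        coords.append(pos)
        radii.append(radii_table[el])
        het.append(True)
    structure = Structure(
        atom_names=atom_names,
        elements=elements,
        res_names=res_names,
        res_seq=np.array(res_seq),
        chain_ids=["A"] * len(atom_names),
        coords=np.round(np.array(coords), 3),  # PDB precision
        radii=np.array(radii),
        occupancies=np.ones(len(atom_names)),
        is_hetero=np.array(het),
    )
    return ToyComplex(
        structure=structure,
        pdb_text=write_pdb(structure),
        ligand_mask=structure.is_hetero.copy(),
        group_depths=list(ligand_spec.depths),
        pocket_classes=pocket,
        params={"seed": seed, "n_protein_atoms": n_protein_atoms,
                "fraction_hydrophobic": fraction_hydrophobic},
    )


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
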