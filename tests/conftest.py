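"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from phspec.properties import load_scale
from phspec.structure import Structure


@pytest.fixture(scope="session")
def scales():
    return {s: load_scale(s) for s in ("H", "F", "E", "I")}


def make_structure(coords, radii, elements=None, het=None, names=None,
                   res_names=None, res_seq=None):
    """Minimal Structure from raw arrays (one residue per atom)."""
    n = len(radii)
    coords = np.asarray(coords, dtype=float)
    return Structure(
        atom_names=names or [f"X{i}" for i in range(n)],
        elements=elements or ["C"] * n,
        res_names=res_names or ["UNK"] * n,
        res_seq=np.asarray(res_seq if res_seq is not None
                           else np.arange(1, n + 1)),
        chain_ids=["A"] * n,
        coords=coords,
        radii=np.asarray(radii, dtype=float),
        occupancies=np.ones(n),
        is_hetero=np.asarray(het if het is not None else [False] * n),
    )


def sampling_sasa_oracle(coords, radii, probe, n_points, rng):
    """Independent Shrake-Rupley-style SASA estimate (random points)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    rexp = radii + probe
    n = len(radii)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    areas = np.zeros(n)
    for i in range(n):
        p = coords[i] + rexp[i] * pts
        acc = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", p - coords[j], p - coords[j])
            acc &= d2 >= rexp[j] ** 2
        areas[i] = acc.mean() * 4.0 * np.pi * rexp[i] ** 2
    return areas


def attribution_oracle(group, structure, ligand_mask, classes, legitimacy,
                       probe, n_points, rng):
    """Dense random-sampling legitimate/illegitimate partition oracle.

    Buried surface points of each group atom (accessible on the
    isolated ligand, occluded by protein) are each assigned to the
    protein atom with the nearest expanded surface.
    """
    coords = structure.coords
    rexp = structure.radii + probe
    lig_idx = np.flatnonzero(ligand_mask)
    prot_idx = np.flatnonzero(~np.asarray(ligand_mask))
    s_legit = s_illegit = buried = 0.0
    for ai in group.atom_indices:
        ra = rexp[ai]
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[ai] + ra * pts
        app = 4.0 * np.pi * ra * ra / n_points
        acc = np.ones(n_points, dtype=bool)
        for j in lig_idx:
            if j == ai:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            acc &= d2 >= rexp[j] ** 2
        if not acc.any() or len(prot_idx) == 0:
            continue
        pp = pts[acc]
        d = np.linalg.norm(pp[:, None, :] - coords[prot_idx][None, :, :],
                           axis=2)
        inside = (d < rexp[prot_idx][None, :]).any(axis=1)
        if not inside.any():
            continue
        buried += inside.sum() * app
        surf = d[inside] - rexp[prot_idx][None, :]
        owners = prot_idx[np.argmin(surf, axis=1)]
        for po in owners:
            if legitimacy[(classes[ai], classes[po])]:
                s_legit += app
            else:
                s_illegit += app
    return s_legit, s_illegit, buried
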