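"""Physicochemical sequence profiles.

PH domains share very low sequence identity, so comparisons are made on
per-position profiles of physicochemical properties (hydropathy,
flexibility, electronic charge concentration, isotropic surface area)
smoothed with a sliding window, and mapped onto a common multiple
alignment.  This module provides the property scales, the window
smoothing operator, and the alignment-coordinate bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: nonstandard one-letter codes handled by the mean-value policy
NONSTANDARD_LETTERS = frozenset("XBZUO")

#: short label -> packaged scale file
BUILTIN_SCALES = {
    "H": "hydropathy.tsv",
    "F": "flexibility.tsv",
    "E": "electronic_charge.tsv",
    "I": "isotropic_surface_area.tsv",
}

_GAP_CHARS = "-."


def _data_path(*parts: str):
    return resources.files("phspec").joinpath("data", *parts)


@dataclass(frozen=True)
class PropertyScale:
    """An immutable amino-acid -> value mapping.

    Lookups of nonstandard letters (X, B, Z, U, O) return the mean of
    the 20 standard values, with a warning; this keeps profiles defined
    without biasing toward any residue class.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        letters = set(self.values)
        missing = sorted(set(STANDARD_AMINO_ACIDS) - letters)
        if missing:
            raise ValueError(
                f"scale {self.name!r} is missing amino acids: {''.join(missing)}"
            )
        extra = sorted(letters - set(STANDARD_AMINO_ACIDS))
        if extra:
            raise ValueError(
                f"scale {self.name!r} has non-standard entries: {''.join(extra)}"
            )
        object.__setattr__(self, "values", dict(self.values))

    @property
    def mean(self) -> float:
        return float(np.mean([self.values[a] for a in STANDARD_AMINO_ACIDS]))

    def value(self, letter: str) -> float:
        """Scale value for one residue letter (case-insensitive)."""
        aa = letter.upper()
        if aa in self.values:
            return self.values[aa]
        if aa in NONSTANDARD_LETTERS:
            warnings.warn(
                f"nonstandard residue {aa!r}: using mean of scale {self.name!r}",
                stacklevel=2,
            )
            return self.mean
        raise KeyError(f"unknown residue letter {letter!r}")

    def encode(self, sequence: str) -> np.ndarray:
        """Per-residue raw values for a one-letter sequence."""
        return np.array([self.value(a) for a in sequence], dtype=float)


def load_scale(source: str | Path) -> PropertyScale:
    """Load a property scale from a built-in name or a two-column file.

    ``source`` may be one of the built-in labels ``H`` (hydropathy,
    Kyte-Doolittle), ``F`` (flexibility, Vihinen normalized B-factors),
    ``E`` (electronic charge concentration, Collantes-Dunn ECI) or
    ``I`` (isotropic surface area, Collantes-Dunn ISA), or the path of
    a whitespace-delimited two-column text table (``#`` comments).

    Raises
    ------
    ValueError
        If an amino acid is missing or listed twice.
    """
    if isinstance(source, str) and source in BUILTIN_SCALES:
        text = _data_path("scales", BUILTIN_SCALES[source]).read_text()
        name = source
    else:
        text = Path(source).read_text()
        name = Path(source).stem
    values: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{name}: line {lineno}: expected 'AA value'")
        aa, raw = fields[0].upper(), fields[1]
        if aa in values:
            raise ValueError(f"{name}: duplicate entry for {aa!r}")
        values[aa] = float(raw)
    return PropertyScale(name=name, values=values)


@dataclass(frozen=True)
class SequenceProfile:
    """Sliding-window averaged property values along one sequence."""

    sequence_id: str
    residues: str
    window: int
    values: np.ndarray
    scale_name: str

    def __post_init__(self):
        if len(self.values) != len(self.residues):
            raise ValueError("profile length != sequence length")


def sliding_window_mean(raw: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with end truncation.

    Position ``i`` holds the mean of the raw values over the window of
    half-width ``(window - 1) // 2`` centred at ``i``, truncated at the
    sequence ends (mean over the available positions only).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    n = len(raw)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_profile(
    sequence: str,
    scale: PropertyScale,
    window: int = 9,
    sequence_id: str = "",
) -> SequenceProfile:
    """Smoothed physicochemical profile of one ungapped sequence.

    With ``window == 1`` the profile equals the raw per-residue scale
    values exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    raw = scale.encode(sequence)
    return SequenceProfile(
        sequence_id=sequence_id,
        residues=sequence,
        window=window,
        values=sliding_window_mean(raw, window),
        scale_name=scale.name,
    )


def normalize_gaps(row: str) -> str:
    """Normalize '.' gap characters to '-'."""
    return "".join("-" if c in _GAP_CHARS else c for c in row)


def column_map(gapped_row: str) -> np.ndarray:
    """Alignment column -> residue index, -1 at gap columns.

    Non-gap mappings are strictly increasing by construction.
    """
    out = np.full(len(gapped_row), -1, dtype=int)
    k = 0
    for j, c in enumerate(gapped_row):
        if c not in _GAP_CHARS:
            out[j] = k
            k += 1
    return out


@dataclass
class AlignmentProfileSet:
    """Per-sequence profiles laid out on alignment columns.

    ``profiles[seq_id][scale_name]`` is an array of length
    ``n_columns`` with NaN at gap cells.
    """

    alignment: dict[str, str]
    column_maps: dict[str, np.ndarray] = field(default_factory=dict)
    profiles: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values())))


def map_profiles_to_alignment(
    profiles: Sequence[SequenceProfile],
    alignment: Mapping[str, str],
) -> AlignmentProfileSet:
    """Place per-residue profile values at their alignment columns.

    Every profile's ungapped sequence must equal the corresponding
    alignment row with gaps removed; gap cells carry NaN.
    """
    aln = {k: normalize_gaps(v) for k, v in alignment.items()}
    lengths = {len(v) for v in aln.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    out = AlignmentProfileSet(alignment=aln)
    for seq_id, row in aln.items():
        out.column_maps[seq_id] = column_map(row)
    for prof in profiles:
        if prof.sequence_id not in aln:
            raise KeyError(f"profile {prof.sequence_id!r} not in alignment")
        row = aln[prof.sequence_id]
        ungapped = row.replace("-", "")
        if ungapped != prof.residues.upper():
            for i, (a, b) in enumerate(zip(ungapped, prof.residues.upper())):
                if a != b:
                    raise ValueError(
                        f"{prof.sequence_id}: alignment/sequence mismatch at "
                        f"residue index {i}: {a!r} != {b!r}"
                    )
            raise ValueError(
                f"{prof.sequence_id}: alignment/sequence length mismatch "
                f"({len(ungapped)} vs {len(prof.residues)})"
            )
        cmap = out.column_maps[prof.sequence_id]
        placed = np.full(len(row), np.nan)
        nongap = cmap >= 0
        placed[nongap] = prof.values[cmap[nongap]]
        out.profiles.setdefault(prof.sequence_id, {})[prof.scale_name] = placed
    return out


def average_pairwise_identity(alignment: Mapping[str, str]) -> float:
    """Mean pairwise sequence identity of a gapped alignment.

    For each unordered pair of rows, identity = identical aligned
    residue pairs / columns where both rows are non-gap
    (pairwise-deletion denominator).  Pairs with no shared non-gap
    column are excluded with a warning.
    """
    rows = [normalize_gaps(v).upper() for v in alignment.values()]
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.array([list(r) for r in rows])
    nongap = mat != "-"
    idents = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            if denom == 0:
                warnings.warn(
                    f"rows {i} and {j} share no aligned columns; pair excluded"
                )
                continue
            idents.append((mat[i][both] == mat[j][both]).sum() / denom)
    if not idents:
        raise ValueError("no comparable row pairs")
    return float(np.mean(idents))
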