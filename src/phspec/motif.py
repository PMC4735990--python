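"""Sequence-motif scanning.

The first branch of the binding-specificity decision flow asks whether
a PH-domain sequence carries the signature motif for 3-phosphate
binding in or near its beta1/beta2 loop.  Patterns are restricted
regular expressions over amino-acid letters: literals, character sets,
and bounded gaps only (PROSITE-style ``X(n,m)`` gaps are accepted and
translated); unbounded repeats are rejected so every pattern has a
bounded match length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

_UNBOUNDED = re.compile(r"[*+]|\{\d+,\}")


@dataclass(frozen=True)
class MotifPattern:
    """A named, bounded sequence pattern."""

    name: str
    pattern: str  # as written (PROSITE-like or plain regex)
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "_regex", re.compile(self.to_regex()))

    def to_regex(self) -> str:
        """Translate PROSITE-style tokens to a Python regex."""
        pat = self.pattern.replace("-", "")
        pat = re.sub(r"[Xx]\((\d+),(\d+)\)", r".{\1,\2}", pat)
        pat = re.sub(r"[Xx]\((\d+)\)", r".{\1}", pat)
        pat = re.sub(r"(?<![{\d,])[Xx](?![\d,}])", ".", pat)
        if _UNBOUNDED.search(pat):
            raise ValueError(f"pattern {self.pattern!r} has an unbounded repeat")
        return pat

    @property
    def regex(self) -> re.Pattern:
        return self._regex  # type: ignore[attr-defined]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on an ungapped sequence (0-based, half-open)."""

    sequence_id: str
    start: int
    end: int
    matched: str
    in_loop: bool


def default_patterns() -> list[MotifPattern]:
    """The packaged 3-phosphate-binding signature pattern(s)."""
    text = resources.files("phspec").joinpath("data", "motifs.txt").read_text()
    return parse_pattern_file(text)


def parse_pattern_file(text: str) -> list[MotifPattern]:
    """Parse a 'name<TAB>pattern' file ('#' comments)."""
    patterns = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        name, pat = line.split(None, 1)
        patterns.append(MotifPattern(name=name, pattern=pat.strip()))
    return patterns


def load_patterns(path: str | Path) -> list[MotifPattern]:
    return parse_pattern_file(Path(path).read_text())


def scan_motif(
    sequence: str,
    pattern: MotifPattern,
    loop_window: tuple[int, int] | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All non-overlapping leftmost matches, ordered by start.

    ``loop_window`` is a half-open residue-index range; a hit is
    flagged ``in_loop`` when its span intersects that range.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    hits = []
    for m in pattern.regex.finditer(seq):
        in_loop = False
        if loop_window is not None:
            lo, hi = loop_window
            in_loop = m.start() < hi and m.end() > lo
        hits.append(
            MotifHit(
                sequence_id=sequence_id,
                start=m.start(),
                end=m.end(),
                matched=m.group(0),
                in_loop=in_loop,
            )
        )
    return hits
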