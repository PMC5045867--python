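"""Dibasic cleavage motifs shared by the motif feature and the rule-based
known-motif baseline, so the two can never disagree.

The classic proprotein-convertase patterns describe the 4-mer ending at the
putative cleavage site (cleavage is C-terminal to the basic pair):

    X-X-K-[K or R]
    X-X-R-R
    R-X-X-[K or R]

where X matches any residue (including pads and unknowns, which only ever
occupy wildcard positions).
"""

from __future__ import annotations

import re
from typing import Sequence

#: The three dibasic patterns as anchored regular expressions over a 4-mer.
KNOWN_MOTIF_PATTERNS: tuple[str, ...] = (
    r"^..K[KR]$",
    r"^..RR$",
    r"^R..[KR]$",
)

_COMPILED = tuple(re.compile(p, re.DOTALL) for p in KNOWN_MOTIF_PATTERNS)


def site_fourmer(residues: str, site_offset: int) -> str:
    """The 4-mer occupying window positions ``X-3 .. X`` (0-based offset of
    the site = ``site_offset``), left-padded with ``.``-matching blanks when
    the window geometry leaves fewer than 3 preceding positions."""
    lo = site_offset - 3
    prefix = "_" * max(0, -lo)
    return prefix + residues[max(lo, 0) : site_offset + 1]


def match_known_motifs(fourmer: str) -> int:
    """Number of the three dibasic patterns matching a 4-mer (0..3)."""
    if len(fourmer) != 4:
        raise ValueError(f"expected a 4-mer, got {fourmer!r}")
    return sum(1 for rx in _COMPILED if rx.match(fourmer))


def matches_any(fourmer: str) -> bool:
    return match_known_motifs(fourmer) > 0


def count_nonoverlapping(pattern: str, s: str) -> int:
    """Leftmost non-overlapping occurrence count of ``pattern`` in ``s``."""
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {pattern!r}: {exc}") from exc
    return sum(1 for _ in rx.finditer(s))


#: Default cysteine spacer pattern: C, 2-6 non-cysteine residues, C.
CYS_SPACER_PATTERN = r"C[^C]{2,6}C"
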