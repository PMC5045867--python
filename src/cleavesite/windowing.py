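"""Fixed-length window extraction, candidate filtering and deduplication.

Every residue of a protein yields one window: the residue itself (the
putative site), the ``w_pre`` residues before it and the ``w_suf`` residues
after it.  Positions beyond the termini are filled with a pad symbol, so
the window centered on residue 1 of a protein carries ``w_pre`` pads.  With
the default geometry (11 before, 8 after) every window has length 20.

Candidate filtering keeps dibasic-cleavage candidates: windows whose site
residue is K or R and which lie at least ``min_terminal_distance`` residues
away from either terminus.  Deduplication collapses windows sharing the
identity key (the site flanked by ``dedup_radius`` residues on each side,
an 11-mer by default); when duplicates disagree on the label, the cleaved
(1) label wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .seq_io import AA_ALPHABET, AnnotatedSequence, BackgroundFrequencies, load_background

#: Symbol a pad position carries in ss/acc/disorder track slices.
TRACK_PAD = "-"


@dataclass(frozen=True)
class WindowConfig:
    """Geometry and filtering parameters for window extraction."""

    w_pre: int = 11
    w_suf: int = 8
    pad_symbol: str = "_"
    center_alphabet: frozenset[str] = frozenset({"K", "R"})
    min_terminal_distance: int = 4
    dedup_radius: int = 5

    def __post_init__(self) -> None:
        if self.w_pre < 0 or self.w_suf < 0:
            raise ValueError("window extents must be non-negative")
        if self.dedup_radius > min(self.w_pre, self.w_suf):
            raise ValueError("dedup_radius must not exceed min(w_pre, w_suf)")
        if len(self.pad_symbol) != 1 or self.pad_symbol in AA_ALPHABET:
            raise ValueError("pad_symbol must be a single non-amino-acid character")

    @property
    def length(self) -> int:
        """Total window length ``w_pre + 1 + w_suf``."""
        return self.w_pre + 1 + self.w_suf

    @property
    def site_offset(self) -> int:
        """0-based index of the putative site within the window."""
        return self.w_pre


@dataclass
class Window:
    """A padded fixed-length subsequence centered on a putative site.

    ``site_index`` is the 1-based position of the site in the parent
    sequence; ``residues`` has length ``w_pre + 1 + w_suf`` and may contain
    the pad symbol only as a contiguous prefix and/or suffix.  Track and
    PSSM slices, when present, are padded identically: track pads carry
    :data:`TRACK_PAD` and PSSM pad rows carry the background distribution.
    """

    parent_id: str
    site_index: int
    parent_length: int
    residues: str
    label: Optional[int] = None
    ss: Optional[str] = None
    acc: Optional[str] = None
    dis: Optional[str] = None
    pssm: Optional[np.ndarray] = field(default=None, repr=False)

    def site_residue(self, cfg: WindowConfig) -> str:
        return self.residues[cfg.site_offset]


def _pad_slice(s: str, lo: int, hi: int, pad: str) -> str:
    """Slice ``s[lo:hi]`` (0-based, half-open) padding out-of-range with ``pad``."""
    left = max(0, -lo)
    right = max(0, hi - len(s))
    return pad * left + s[max(lo, 0) : min(hi, len(s))] + pad * right


def extract_windows(
    seq: AnnotatedSequence,
    cfg: WindowConfig = WindowConfig(),
    background: Optional[BackgroundFrequencies] = None,
) -> list[Window]:
    """Extract one window per residue of ``seq``.

    Returns exactly ``len(seq)`` windows; window ``i`` (1-based) covers
    parent positions ``i - w_pre .. i + w_suf`` with out-of-range positions
    padded.  The window label is the site residue's label.  PSSM pad rows
    are filled with ``background`` (shipped vertebrate table by default) so
    padding is feature-neutral.
    """
    if len(seq) == 0:
        raise ValueError(f"record {seq.id!r}: empty sequence")
    L = len(seq)
    bg_row = None
    if seq.pssm is not None:
        bg = background if background is not None else load_background()
        bg_row = bg.as_array()
    out = []
    for i in range(1, L + 1):
        lo, hi = i - 1 - cfg.w_pre, i + cfg.w_suf  # 0-based half-open
        residues = _pad_slice(seq.residues, lo, hi, cfg.pad_symbol)
        w = Window(
            parent_id=seq.id,
            site_index=i,
            parent_length=L,
            residues=residues,
            label=None if seq.labels is None else int(seq.labels[i - 1]),
            ss=None if seq.ss_track is None else _pad_slice(seq.ss_track, lo, hi, TRACK_PAD),
            acc=None if seq.acc_track is None else _pad_slice(seq.acc_track, lo, hi, TRACK_PAD),
            dis=None if seq.dis_track is None else _pad_slice(seq.dis_track, lo, hi, TRACK_PAD),
        )
        if seq.pssm is not None:
            rows = np.tile(bg_row, (cfg.length, 1))
            src_lo, src_hi = max(lo, 0), min(hi, L)
            rows[src_lo - lo : src_lo - lo + (src_hi - src_lo)] = seq.pssm[src_lo:src_hi]
            w.pssm = rows
        out.append(w)
    return out


def filter_candidates(
    windows: Sequence[Window], cfg: WindowConfig = WindowConfig()
) -> list[Window]:
    """Keep putative-site candidates: center residue in ``center_alphabet``
    and site index ``i`` with ``i > d`` and ``i <= L - d`` for
    ``d = min_terminal_distance`` (at least ``d`` real residues on each side).
    """
    d = cfg.min_terminal_distance
    return [
        w
        for w in windows
        if w.site_residue(cfg) in cfg.center_alphabet
        and w.site_index > d
        and w.site_index <= w.parent_length - d
    ]


def dedup_key(window: Window, cfg: WindowConfig = WindowConfig()) -> str:
    """Identity key: the site flanked by ``dedup_radius`` residues per side."""
    c = cfg.site_offset
    return window.residues[c - cfg.dedup_radius : c + cfg.dedup_radius + 1]


def dedupe_windows(
    windows: Sequence[Window], cfg: WindowConfig = WindowConfig()
) -> list[Window]:
    """Collapse windows sharing a dedup key to one representative.

    The representative is the first-encountered member (stable input
    order); its label is 1 if any member is labeled 1, else 0 — duplicates
    with conflicting labels resolve to the cleaved label.
    """
    reps: dict[str, Window] = {}
    for w in windows:
        key = dedup_key(w, cfg)
        if key not in reps:
            reps[key] = w
        elif w.label == 1 and reps[key].label != 1:
            reps[key] = replace(reps[key], label=1)
    return list(reps.values())


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped sliding-alignment identity: best-offset match count divided
    by the shorter length."""
    if not a or not b:
        return 0.0
    best = 0
    for off in range(-(len(b) - 1), len(a)):
        matches = sum(
            1
            for j in range(max(0, -off), min(len(b), len(a) - off))
            if b[j] == a[j + off]
        )
        best = max(best, matches)
    return best / min(len(a), len(b))


def reduce_redundancy_greedy(
    seqs: Sequence[AnnotatedSequence], max_identity: float = 0.60
) -> list[AnnotatedSequence]:
    """Greedy whole-protein redundancy reduction.

    Scans sequences in input order and keeps one iff its identity to every
    previously kept sequence is <= ``max_identity``.  This approximates the
    usual clustering-based reduction (CD-HIT/USEARCH style) with a
    deterministic, order-stable rule; externally computed cluster files may
    be used instead via the CLI.
    """
    kept: list[AnnotatedSequence] = []
    for s in seqs:
        if all(pairwise_identity(s.residues, k.residues) <= max_identity for k in kept):
            kept.append(s)
    return kept
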