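"""Readers and writers for sequences, per-residue labels, annotation tracks
and PSSM frequency profiles.

The labeled-file ("lf") format pairs each protein sequence with an aligned
string of per-residue 0/1 labels:

    >{id}
    {SEQUENCE}
    {LABELS}

Annotation-track files use the same three-line shape with the track alphabet
(``HEC`` for secondary structure, ``be`` for solvent accessibility, ``01``
for disorder) in place of the labels.  PSSM files carry a ``#id`` header
followed by L whitespace-separated rows of 20 frequencies in alphabetical
one-letter order (``ACDEFGHIKLMNPQRSTVWY``); a custom column order may be
supplied.  All coordinates in this package are 1-based.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

#: The canonical 20-letter amino-acid alphabet, alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabets of the supported per-residue annotation tracks.
TRACK_ALPHABETS = {"ss": "HEC", "acc": "be", "disorder": "01"}

_PSSM_RENORM_TOL = 1e-3


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


@dataclass
class AnnotatedSequence:
    """A protein with optional per-residue labels, annotation tracks and PSSM.

    Attributes
    ----------
    id : str
        Record identifier.
    residues : str
        Amino-acid sequence over the 20-letter alphabet; unknown residues
        are written ``X``.
    labels : str, optional
        Per-residue binary labels (``0``/``1``), same length as ``residues``.
    ss_track, acc_track, dis_track : str, optional
        Per-residue secondary-structure ({H,E,C}), solvent-accessibility
        ({b,e}) and disorder ({0,1}) annotations.
    pssm : ndarray, optional
        L x 20 row-stochastic matrix of amino-acid frequencies, columns in
        :data:`AA_ALPHABET` order.
    """

    id: str
    residues: str
    labels: Optional[str] = None
    ss_track: Optional[str] = None
    acc_track: Optional[str] = None
    dis_track: Optional[str] = None
    pssm: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        L = len(self.residues)
        for name, track, alpha in (
            ("labels", self.labels, "01"),
            ("ss_track", self.ss_track, TRACK_ALPHABETS["ss"]),
            ("acc_track", self.acc_track, TRACK_ALPHABETS["acc"]),
            ("dis_track", self.dis_track, TRACK_ALPHABETS["disorder"]),
        ):
            if track is None:
                continue
            if len(track) != L:
                raise FormatError(
                    f"record {self.id!r}: {name} length {len(track)} != sequence length {L}"
                )
            bad = set(track) - set(alpha)
            if bad:
                raise FormatError(
                    f"record {self.id!r}: illegal {name} symbol(s) {sorted(bad)}"
                )
        if self.pssm is not None:
            self.pssm = np.asarray(self.pssm, dtype=float)
            if self.pssm.shape != (L, 20):
                raise FormatError(
                    f"record {self.id!r}: PSSM shape {self.pssm.shape} != ({L}, 20)"
                )
            if (self.pssm < 0).any():
                raise FormatError(f"record {self.id!r}: negative PSSM entry")
            sums = self.pssm.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise FormatError(f"record {self.id!r}: PSSM rows do not sum to 1")


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background amino-acid frequencies of naturally occurring proteins."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(AA_ALPHABET):
            raise ValueError("background must cover exactly the 20 canonical residues")
        vals = np.array([self.freq[a] for a in AA_ALPHABET])
        if (vals <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def as_array(self) -> np.ndarray:
        """Frequencies as a length-20 vector in :data:`AA_ALPHABET` order."""
        return np.array([self.freq[a] for a in AA_ALPHABET])


def _data_path(*parts: str):
    return importlib.resources.files("cleavesite").joinpath("data", *parts)


def _read_aa_table(path) -> dict[str, float]:
    table: dict[str, float] = {}
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    return table


def load_background(path: Optional[str | Path] = None) -> BackgroundFrequencies:
    """Load background frequencies from a TSV (default: shipped vertebrate table).

    Values are renormalised to sum exactly to 1.
    """
    src = _data_path("background_vertebrate.tsv") if path is None else Path(path)
    table = _read_aa_table(src)
    total = sum(table.values())
    return BackgroundFrequencies({aa: v / total for aa, v in table.items()})


def uniform_background() -> BackgroundFrequencies:
    """Uniform background: every residue at frequency 1/20."""
    return BackgroundFrequencies({aa: 1.0 / 20 for aa in AA_ALPHABET})


# ---------------------------------------------------------------------------
# lf (labeled file) format
# ---------------------------------------------------------------------------

def _iter_three_line_records(path: str | Path) -> Iterable[tuple[str, str, str]]:
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 3:
        raise FormatError(f"{path}: record count is not a multiple of 3 lines")
    for k in range(0, len(lines), 3):
        header, seq, anno = lines[k : k + 3]
        if not header.startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {header[:30]!r}")
        yield header[1:].strip(), seq.strip().upper(), anno.strip()


def read_lf(path: str | Path) -> list[AnnotatedSequence]:
    """Read a labeled file into a list of :class:`AnnotatedSequence`.

    An empty file yields an empty list.  A label string whose length does
    not match its sequence, or containing symbols other than 0/1, raises
    :class:`FormatError` naming the record.
    """
    out = []
    for rec_id, seq, labels in _iter_three_line_records(path):
        if len(labels) != len(seq):
            raise FormatError(
                f"record {rec_id!r}: labels length {len(labels)} != sequence length {len(seq)}"
            )
        out.append(AnnotatedSequence(id=rec_id, residues=seq, labels=labels))
    return out


def write_lf(seqs: list[AnnotatedSequence], path: str | Path) -> None:
    """Write labeled sequences in the lf dialect readable by :func:`read_lf`."""
    chunks = []
    for s in seqs:
        if s.labels is None:
            raise ValueError(f"record {s.id!r} has no labels; cannot write lf")
        chunks.append(f">{s.id}\n{s.residues}\n{s.labels}\n")
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# FASTA (prediction-mode input)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read FASTA sequences (labels absent); uppercases and strips ``*``."""
    out = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        residues = str(rec.seq).upper().replace("*", "").replace(" ", "")
        out.append(AnnotatedSequence(id=rec.id, residues=residues))
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"duplicate FASTA ids: {dupes}")
    return out


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

def read_pssm(
    path: str | Path,
    seq: AnnotatedSequence,
    column_order: str = AA_ALPHABET,
) -> AnnotatedSequence:
    """Attach a PSSM frequency profile to ``seq``.

    The file holds a ``#id`` header then L rows of 20 floats, columns in
    ``column_order``.  Rows are renormalised to sum exactly to 1 when within
    1e-3 of 1; anything further off is a :class:`FormatError`.
    """
    if sorted(column_order) != sorted(AA_ALPHABET):
        raise ValueError("column_order must be a permutation of the 20 residues")
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2 or mat.shape != (len(seq), 20):
        raise FormatError(
            f"PSSM {path}: got shape {mat.shape if mat.ndim == 2 else len(rows)}, "
            f"expected ({len(seq)}, 20)"
        )
    if (mat < 0).any():
        raise FormatError(f"PSSM {path}: negative frequency")
    sums = mat.sum(axis=1)
    off = np.abs(sums - 1.0)
    if (off > _PSSM_RENORM_TOL).any():
        bad = int(np.argmax(off)) + 1
        raise FormatError(
            f"PSSM {path}: row {bad} sums to {sums[bad - 1]:.4f}, beyond the "
            f"renormalization tolerance {_PSSM_RENORM_TOL}"
        )
    mat = mat / sums[:, None]
    # reorder columns into canonical alphabetical order
    perm = [column_order.index(a) for a in AA_ALPHABET]
    return replace(seq, pssm=mat[:, perm])


def write_pssm(seq: AnnotatedSequence, path: str | Path) -> None:
    if seq.pssm is None:
        raise ValueError(f"record {seq.id!r} has no PSSM")
    lines = [f"#id {seq.id}"]
    for row in seq.pssm:
        lines.append(" ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

_TRACK_ATTR = {"ss": "ss_track", "acc": "acc_track", "disorder": "dis_track"}


def read_tracks(
    path: str | Path, kind: str, seqs: list[AnnotatedSequence]
) -> list[AnnotatedSequence]:
    """Attach per-residue annotation tracks (``ss``, ``acc`` or ``disorder``).

    Track files share the lf three-line shape with the track alphabet in
    place of labels.  Records are matched to ``seqs`` by id; every sequence
    must receive a track.
    """
    if kind not in _TRACK_ATTR:
        raise ValueError(f"unknown track kind {kind!r}; expected one of {sorted(_TRACK_ATTR)}")
    tracks = {rec_id: anno for rec_id, _, anno in _iter_three_line_records(path)}
    out = []
    for s in seqs:
        if s.id not in tracks:
            raise FormatError(f"track file {path} has no record for {s.id!r}")
        out.append(replace(s, **{_TRACK_ATTR[kind]: tracks[s.id]}))
    return out


def write_tracks(seqs: list[AnnotatedSequence], kind: str, path: str | Path) -> None:
    attr = _TRACK_ATTR[kind]
    chunks = []
    for s in seqs:
        track = getattr(s, attr)
        if track is None:
            raise ValueError(f"record {s.id!r} has no {kind} track")
        chunks.append(f">{s.id}\n{s.residues}\n{track}\n")
    Path(path).write_text("".join(chunks))
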