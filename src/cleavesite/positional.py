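"""Per-position window features.

Families
--------
* one-hot encodings of residue identity (full 20-letter or 15-group reduced
  alphabet) and of the ss / acc / disorder annotation tracks;
* electric charge (+1 for K and R, -1 for D and E, 0 otherwise — histidine
  is treated as neutral by default);
* PSSM frequencies (the 20 profile values at each position);
* PSSM conservation, the relative entropy (KL divergence) of each profile
  column against background frequencies:  sum_i p_i * log(p_i / pb_i);
* a FoldIndex-style disorder heuristic combining mean hydropathy and mean
  net charge over a local neighbourhood.

Pad positions are feature-neutral: one-hot columns are all zero, charge is
0, PSSM columns carry the background distribution (hence zero relative
entropy) and FoldIndex neighbourhoods skip them.

Feature names follow ``{family}_pos{j}_{symbol}`` with ``j`` the 1-based
window position — stable across runs for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .seq_io import AA_ALPHABET, BackgroundFrequencies, _data_path
from .windowing import TRACK_PAD, Window, WindowConfig

# Kyte-Doolittle hydropathy (used by the FoldIndex heuristic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# FoldIndex constants from the original unfoldability formula
# 2.785 <H> - |<q>| - 1.151.
FOLDINDEX_HYDRO_COEF = 2.785
FOLDINDEX_INTERCEPT = 1.151

CHARGE = {**{aa: 0.0 for aa in AA_ALPHABET}, "K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass
class FeatureVector:
    """Named feature values; names are unique and order is deterministic."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    @staticmethod
    def concat(parts: list["FeatureVector"]) -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names on concatenation")
        return FeatureVector(names, np.concatenate([p.values for p in parts]) if parts else np.array([]))


@dataclass(frozen=True)
class ReducedAlphabet:
    """An ordered partition of the 20 amino acids into 15 groups."""

    name: str
    groups: tuple[tuple[str, str], ...]  # (group name, member residues)

    def __post_init__(self) -> None:
        members = "".join(g for _, g in self.groups)
        if len(self.groups) != 15:
            raise ValueError("reduced alphabet must have exactly 15 groups")
        if sorted(members) != sorted(AA_ALPHABET):
            raise ValueError("groups must partition the 20 amino acids")

    def group_of(self, aa: str) -> Optional[str]:
        for gname, members in self.groups:
            if aa in members:
                return gname
        return None

    @property
    def group_names(self) -> list[str]:
        return [g for g, _ in self.groups]


def load_reduced_alphabet(path: Optional[str | Path] = None) -> ReducedAlphabet:
    """Load a reduced alphabet from TSV ``group<TAB>members`` (default: the
    shipped 15-group table)."""
    src = _data_path("reduced15.tsv") if path is None else Path(path)
    groups = []
    for line in Path(str(src)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gname, members = line.split("\t")
        groups.append((gname, members))
    return ReducedAlphabet(name=Path(str(src)).stem, groups=tuple(groups))


def _positions(cfg: WindowConfig) -> range:
    return range(1, cfg.length + 1)


def one_hot_positional(
    window: Window,
    alphabet: str = "full",
    cfg: WindowConfig = WindowConfig(),
    reduced: Optional[ReducedAlphabet] = None,
) -> FeatureVector:
    """One-hot encode a discrete per-position property.

    ``alphabet`` selects the source: ``full`` (residue identity over 20
    letters), ``reduced`` (15 groups), or an annotation track (``ss``,
    ``acc``, ``disorder``).  Pad positions (and unknown ``X`` residues)
    encode as all-zeros.
    """
    if alphabet == "full":
        symbols, track, fam = list(AA_ALPHABET), window.residues, "aa"
        code = {s: k for k, s in enumerate(symbols)}
    elif alphabet == "reduced":
        ra = reduced if reduced is not None else load_reduced_alphabet()
        symbols, track, fam = ra.group_names, window.residues, "red"
        code = {aa: ra.group_names.index(ra.group_of(aa)) for aa in AA_ALPHABET}
    elif alphabet in ("ss", "acc", "disorder"):
        attr = {"ss": "ss", "acc": "acc", "disorder": "dis"}[alphabet]
        track = getattr(window, attr)
        if track is None:
            raise ValueError(
                f"window {window.parent_id}:{window.site_index} lacks the "
                f"{alphabet!r} track required for its one-hot features"
            )
        symbols = {"ss": list("HEC"), "acc": list("be"), "disorder": list("01")}[alphabet]
        fam = alphabet
        code = {s: k for k, s in enumerate(symbols)}
    else:
        raise ValueError(f"unknown one-hot alphabet {alphabet!r}")

    mat = np.zeros((cfg.length, len(symbols)))
    for j, sym in enumerate(track):
        k = code.get(sym)
        if k is not None:
            mat[j, k] = 1.0
    names = [f"{fam}_pos{j}_{s}" for j in _positions(cfg) for s in symbols]
    return FeatureVector(names, mat.ravel())


def charge_positional(window: Window, cfg: WindowConfig = WindowConfig()) -> FeatureVector:
    """Per-position electric charge: K,R -> +1; D,E -> -1; else 0."""
    vals = np.array([CHARGE.get(s, 0.0) for s in window.residues])
    return FeatureVector([f"charge_pos{j}" for j in _positions(cfg)], vals)


def pssm_positional(window: Window, cfg: WindowConfig = WindowConfig()) -> FeatureVector:
    """The 20 PSSM frequencies at each window position (background at pads)."""
    if window.pssm is None:
        raise ValueError(
            f"window {window.parent_id}:{window.site_index} lacks a PSSM "
            "required for pssm features"
        )
    names = [f"pssm_pos{j}_{a}" for j in _positions(cfg) for a in AA_ALPHABET]
    return FeatureVector(names, np.asarray(window.pssm).ravel())


def pssm_relative_entropy(p: np.ndarray, pb: BackgroundFrequencies) -> float:
    """Relative entropy (KL divergence, nats) of a profile column against
    background:  sum_i p_i * ln(p_i / pb_i), with 0 * ln(0/pb) = 0.

    Low values mean the column resembles background (unconserved); the
    score is non-negative and zero iff p equals the background.
    """
    p = np.asarray(p, dtype=float)
    pbv = pb.as_array()
    if (pbv[p > 0] <= 0).any():
        raise ValueError("undefined divergence: background zero where p > 0")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / pbv[mask])))


def entropy_positional(
    window: Window, background: BackgroundFrequencies, cfg: WindowConfig = WindowConfig()
) -> FeatureVector:
    """Per-position PSSM relative entropy against ``background``."""
    if window.pssm is None:
        raise ValueError(
            f"window {window.parent_id}:{window.site_index} lacks a PSSM "
            "required for entropy features"
        )
    vals = np.array([pssm_relative_entropy(row, background) for row in window.pssm])
    return FeatureVector([f"entropy_pos{j}" for j in _positions(cfg)], vals)


def foldindex_positional(
    window: Window, flank: int = 5, cfg: WindowConfig = WindowConfig()
) -> FeatureVector:
    """FoldIndex-style disorder propensity per position.

    For each position the score is ``2.785 <H> - |<q>| - 1.151`` where
    ``<H>`` is the mean Kyte-Doolittle hydropathy rescaled to [0, 1] and
    ``<q>`` the mean charge, both over the ``flank``-neighbourhood
    (position +/- flank) excluding pad positions.  Negative values indicate
    predicted disorder.
    """
    res = window.residues
    mean_kd = float(np.mean(list(KYTE_DOOLITTLE.values())))
    hyd = [(KYTE_DOOLITTLE.get(s, mean_kd) + 4.5) / 9.0 if s != cfg.pad_symbol else None for s in res]
    chg = [CHARGE.get(s, 0.0) if s != cfg.pad_symbol else None for s in res]
    vals = np.zeros(cfg.length)
    for j in range(cfg.length):
        lo, hi = max(0, j - flank), min(cfg.length, j + flank + 1)
        h = [hyd[k] for k in range(lo, hi) if hyd[k] is not None]
        q = [chg[k] for k in range(lo, hi) if chg[k] is not None]
        if h:
            vals[j] = FOLDINDEX_HYDRO_COEF * np.mean(h) - abs(np.mean(q)) - FOLDINDEX_INTERCEPT
    return FeatureVector([f"foldindex_pos{j}" for j in _positions(cfg)], vals)
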