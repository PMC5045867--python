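"""Segment aggregates, motif counts, global biophysical indices and
amino-acid-scale features over windows.

Segment geometry: with site index X (1-based within the window) and
neighbourhood half-width N, the window tiles into three regions

    [1, X-N-1]   [X-N, X+N]   [X+N+1, L_w]

— upstream context, the immediate neighbourhood of the site, and
downstream context.  Aggregators (min / max / avg) run over each region
with pad positions excluded; a region that is empty or fully padded
yields 0.

Global biophysical indices (molecular weight, isoelectric point, net
charge at a pH grid, aromaticity, instability index, GRAVY, aliphatic
index) follow the standard ExPASy-style formulas and are computed on the
window's real residues, except protein length which refers to the whole
parent protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV

from . import motifs
from .positional import CHARGE, KYTE_DOOLITTLE, FeatureVector
from .seq_io import AA_ALPHABET, _data_path
from .windowing import Window, WindowConfig

_WATER = 18.0153

# Bjellqvist pKa model for charge / isoelectric point (ExPASy-compatible).
_POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PK_CTERMINAL = {"D": 4.55, "E": 4.75}

NET_CHARGE_PH_GRID = (3.0, 5.0, 7.0, 9.0, 11.0)


@dataclass(frozen=True)
class SegmentSpec:
    """Three-region segmentation of a window around its putative site."""

    N: int = 4
    aggregators: tuple[str, ...] = ("min", "max", "avg")

    def segments(self, cfg: WindowConfig) -> list[tuple[int, int]]:
        """1-based inclusive [start, end] bounds of the three regions; the
        regions tile the window without overlap (a degenerate region has
        end < start and yields missing-value 0 features)."""
        X, L = cfg.site_offset + 1, cfg.length
        return [(1, X - self.N - 1), (max(1, X - self.N), min(L, X + self.N)), (X + self.N + 1, L)]


@dataclass(frozen=True)
class AAScale:
    """A propensity scale mapping each amino acid to a number; unknown 'X'
    residues take the mean of the 20 canonical values."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AA_ALPHABET):
            raise ValueError(f"scale {self.name!r} must define exactly the 20 residues")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    def lookup(self, aa: str) -> float:
        if aa == "X":
            return float(np.mean(list(self.values.values())))
        return self.values[aa]


def load_scale(path: str | Path, name: Optional[str] = None) -> AAScale:
    """Load a scale from TSV ``aa<TAB>value`` (20 rows)."""
    table = {}
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, v = line.split("\t")
        table[aa] = float(v)
    return AAScale(name=name or Path(str(path)).stem, values=table)


def default_scales() -> list[AAScale]:
    """The shipped scale set: Kyte-Doolittle hydropathy, Hopp-Woods
    hydrophilicity and the TOP-IDP disorder propensity."""
    return [
        load_scale(_data_path("scales", f"{stem}.tsv"))
        for stem in ("kyte_doolittle", "hopp_woods", "top_idp")
    ]


# ---------------------------------------------------------------------------
# Segment aggregation
# ---------------------------------------------------------------------------

_AGG_FUNCS = {"min": np.min, "max": np.max, "avg": np.mean}


def aggregate_over_segments(
    values: Sequence[float],
    spec: SegmentSpec,
    cfg: WindowConfig = WindowConfig(),
    source: str = "agg",
    pad_mask: Optional[Sequence[bool]] = None,
) -> FeatureVector:
    """Aggregate per-position values over the three site-centered regions.

    ``pad_mask`` marks pad positions (True = pad), which are excluded; a
    region left empty emits 0 with a warning.  Features are named
    ``{source}_seg{k}_{stat}``.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != cfg.length:
        raise ValueError("values must have window length")
    mask = np.zeros(cfg.length, bool) if pad_mask is None else np.asarray(pad_mask, bool)
    names, out = [], []
    for k, (lo, hi) in enumerate(spec.segments(cfg), start=1):
        seg = values[lo - 1 : hi][~mask[lo - 1 : hi]] if hi >= lo else np.array([])
        for stat in spec.aggregators:
            names.append(f"{source}_seg{k}_{stat}")
            if seg.size == 0:
                warnings.warn(
                    f"segment {k} of {source!r} is empty/padded; emitting 0",
                    stacklevel=2,
                )
                out.append(0.0)
            else:
                out.append(float(_AGG_FUNCS[stat](seg)))
    return FeatureVector(names, np.array(out))


# ---------------------------------------------------------------------------
# Motif features
# ---------------------------------------------------------------------------

def known_motif_count(window: Window, cfg: WindowConfig = WindowConfig()) -> FeatureVector:
    """Number of dibasic known-motif patterns (0-3) matching the 4-mer
    ending at the putative site."""
    fourmer = motifs.site_fourmer(window.residues, cfg.site_offset)
    return FeatureVector(["motif_known_count"], np.array([motifs.match_known_motifs(fourmer)]))


def cys_spacer_count(
    window: Window, pattern: str = motifs.CYS_SPACER_PATTERN
) -> FeatureVector:
    """Non-overlapping count of the cysteine spacer motif anywhere in the
    window (default pattern: C, 2-6 non-C residues, C)."""
    n = motifs.count_nonoverlapping(pattern, window.residues)
    return FeatureVector(["motif_cys_spacer"], np.array([float(n)]))


# ---------------------------------------------------------------------------
# Global biophysical indices
# ---------------------------------------------------------------------------

def _charge_at_ph(counts: dict[str, float], nterm: str, cterm: str, ph: float) -> float:
    pos_pks = dict(_POSITIVE_PKS)
    neg_pks = dict(_NEGATIVE_PKS)
    if nterm in _PK_NTERMINAL:
        pos_pks["Nterm"] = _PK_NTERMINAL[nterm]
    if cterm in _PK_CTERMINAL:
        neg_pks["Cterm"] = _PK_CTERMINAL[cterm]
    pos = {"Nterm": 1.0, **{aa: counts.get(aa, 0.0) for aa in ("K", "R", "H")}}
    neg = {"Cterm": 1.0, **{aa: counts.get(aa, 0.0) for aa in ("D", "E", "C", "Y")}}
    charge = 0.0
    for grp, n in pos.items():
        charge += n / (1.0 + 10 ** (ph - pos_pks[grp]))
    for grp, n in neg.items():
        charge -= n / (1.0 + 10 ** (neg_pks[grp] - ph))
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-3) -> float:
    """Isoelectric point by bisection of the Bjellqvist charge model on
    pH in [0, 14] to ``tol`` pH units."""
    counts = {aa: float(peptide.count(aa)) for aa in AA_ALPHABET}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if _charge_at_ph(counts, peptide[0], peptide[-1], mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def global_biophysical(
    window: Window,
    cfg: WindowConfig = WindowConfig(),
    ph_grid: tuple[float, ...] = NET_CHARGE_PH_GRID,
) -> FeatureVector:
    """ExPASy-style global indices of the window's real residues.

    Emits molecular weight (Da), parent protein length (AA), isoelectric
    point, net charge at each pH of ``ph_grid``, aromaticity, instability
    index, GRAVY and aliphatic index.  Unknown 'X' residues contribute
    mean residue mass and mean hydropathy, are excluded from ionizable /
    aromatic / aliphatic counts, and break instability dipeptides.
    """
    pep = window.residues.replace(cfg.pad_symbol, "")
    if not pep:
        raise ValueError("window has no real residues")
    n = len(pep)
    mean_mass = float(np.mean([protein_weights[a] for a in AA_ALPHABET]))
    mw = sum(protein_weights.get(a, mean_mass) for a in pep) - (n - 1) * _WATER

    counts = {aa: float(pep.count(aa)) for aa in AA_ALPHABET}
    pi = isoelectric_point(pep)
    charges = [_charge_at_ph(counts, pep[0], pep[-1], ph) for ph in ph_grid]

    aromaticity = sum(counts[a] for a in "FWY") / n
    if n > 1:
        dip = sum(DIWV[a][b] for a, b in zip(pep, pep[1:]) if a in DIWV and b in DIWV.get(a, {}))
        instability = 10.0 / n * dip
    else:
        instability = 0.0
    mean_kd = float(np.mean(list(KYTE_DOOLITTLE.values())))
    gravy = float(np.mean([KYTE_DOOLITTLE.get(a, mean_kd) for a in pep]))
    aliphatic = 100.0 * (
        counts["A"] / n + 2.9 * counts["V"] / n + 3.9 * (counts["I"] + counts["L"]) / n
    )

    names = ["glob_mw", "glob_length", "glob_pi"]
    vals = [mw, float(window.parent_length), pi]
    for ph, q in zip(ph_grid, charges):
        names.append(f"glob_charge_pH{ph:g}")
        vals.append(q)
    names += ["glob_aromaticity", "glob_instability", "glob_gravy", "glob_aliphatic"]
    vals += [aromaticity, instability, gravy, aliphatic]
    return FeatureVector(names, np.array(vals))


# ---------------------------------------------------------------------------
# Scale features
# ---------------------------------------------------------------------------

def scale_features(
    window: Window,
    scales: Sequence[AAScale],
    spec: SegmentSpec = SegmentSpec(),
    sliding_sizes: tuple[int, ...] = (3, 5, 7),
    cfg: WindowConfig = WindowConfig(),
) -> FeatureVector:
    """Propensity-scale features: per scale, the average over each of the
    three site-centered regions plus sliding overlapping segment averages
    for each size in ``sliding_sizes`` (pad positions excluded; an all-pad
    segment yields 0)."""
    if not scales:
        raise ValueError("scales must be non-empty")
    pad_mask = np.array([s == cfg.pad_symbol for s in window.residues])
    parts = []
    for scale in scales:
        vals = np.array(
            [0.0 if pad else scale.lookup(s) for s, pad in zip(window.residues, pad_mask)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg = aggregate_over_segments(
                vals, SegmentSpec(N=spec.N, aggregators=("avg",)), cfg,
                source=f"scale_{scale.name}", pad_mask=pad_mask,
            )
        parts.append(seg)
        names, out = [], []
        for s in sliding_sizes:
            for off in range(cfg.length - s + 1):
                chunk = vals[off : off + s][~pad_mask[off : off + s]]
                names.append(f"scale_{scale.name}_slide{s}_off{off + 1}")
                out.append(float(chunk.mean()) if chunk.size else 0.0)
        parts.append(FeatureVector(names, np.array(out)))
    return FeatureVector.concat(parts)
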