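"""Feature assembly: concatenate the enabled feature families for each
window into a fixed-length named vector, and stack windows into a feature
matrix (pandas DataFrame) ready for learning.

Two profiles are provided: ``simple`` uses only families computable from
the sequence itself; ``advanced`` additionally uses families derived from
externally supplied inputs (PSSM frequencies and conservation, secondary
structure, solvent accessibility, disorder).  The simple feature-name set
is a strict subset of the advanced one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import aggregate, positional
from .aggregate import AAScale, SegmentSpec
from .positional import FeatureVector, ReducedAlphabet
from .seq_io import BackgroundFrequencies, load_background
from .windowing import Window, WindowConfig

#: Family order is part of the public contract (diffable outputs).
SIMPLE_FAMILIES = (
    "onehot_full",
    "onehot_reduced",
    "charge",
    "charge_agg",
    "foldindex",
    "motif",
    "global",
    "scales",
)
ADVANCED_FAMILIES = SIMPLE_FAMILIES + (
    "pssm",
    "entropy",
    "entropy_agg",
    "onehot_ss",
    "onehot_acc",
    "onehot_disorder",
)


@dataclass
class FeatureConfig:
    """Which families to compute and their shared parameters."""

    profile: str = "simple"
    window: WindowConfig = dc_field(default_factory=WindowConfig)
    segments: SegmentSpec = dc_field(default_factory=SegmentSpec)
    sliding_sizes: tuple[int, ...] = (3, 5, 7)
    foldindex_flank: int = 5
    scales: Optional[Sequence[AAScale]] = None
    reduced: Optional[ReducedAlphabet] = None
    background: Optional[BackgroundFrequencies] = None
    disabled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.profile not in ("simple", "advanced"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def families(self) -> tuple[str, ...]:
        base = SIMPLE_FAMILIES if self.profile == "simple" else ADVANCED_FAMILIES
        return tuple(f for f in base if f not in self.disabled)

    def resolved(self) -> "FeatureConfig":
        """Fill lazy defaults (shipped scales, alphabet and background)."""
        if self.scales is None:
            self.scales = aggregate.default_scales()
        if self.reduced is None:
            self.reduced = positional.load_reduced_alphabet()
        if self.background is None:
            self.background = load_background()
        return self


def assemble_features(window: Window, config: FeatureConfig) -> FeatureVector:
    """Concatenate the enabled family vectors for one window, in fixed
    family order.  Demanding a family whose inputs are missing (PSSM or a
    track) raises a ValueError naming the family."""
    config.resolved()
    cfg = config.window
    pad_mask = np.array([s == cfg.pad_symbol for s in window.residues])
    parts: list[FeatureVector] = []
    for family in config.families:
        if family == "onehot_full":
            parts.append(positional.one_hot_positional(window, "full", cfg))
        elif family == "onehot_reduced":
            parts.append(
                positional.one_hot_positional(window, "reduced", cfg, reduced=config.reduced)
            )
        elif family == "charge":
            parts.append(positional.charge_positional(window, cfg))
        elif family == "charge_agg":
            vals = positional.charge_positional(window, cfg).values
            parts.append(
                _quiet_agg(vals, config.segments, cfg, "charge", pad_mask)
            )
        elif family == "foldindex":
            parts.append(positional.foldindex_positional(window, config.foldindex_flank, cfg))
        elif family == "motif":
            parts.append(
                FeatureVector.concat(
                    [aggregate.known_motif_count(window, cfg), aggregate.cys_spacer_count(window)]
                )
            )
        elif family == "global":
            parts.append(aggregate.global_biophysical(window, cfg))
        elif family == "scales":
            parts.append(
                aggregate.scale_features(
                    window, config.scales, config.segments, config.sliding_sizes, cfg
                )
            )
        elif family == "pssm":
            parts.append(positional.pssm_positional(window, cfg))
        elif family == "entropy":
            parts.append(positional.entropy_positional(window, config.background, cfg))
        elif family == "entropy_agg":
            vals = positional.entropy_positional(window, config.background, cfg).values
            parts.append(_quiet_agg(vals, config.segments, cfg, "entropy", pad_mask))
        elif family.startswith("onehot_"):
            parts.append(positional.one_hot_positional(window, family[len("onehot_"):], cfg))
        else:  # pragma: no cover
            raise ValueError(f"unknown feature family {family!r}")
    return FeatureVector.concat(parts)


def _quiet_agg(vals, spec, cfg, source, pad_mask) -> FeatureVector:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate.aggregate_over_segments(vals, spec, cfg, source, pad_mask)


def build_feature_matrix(
    windows: Sequence[Window], config: FeatureConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack window feature vectors into a matrix.

    Returns ``(X, meta)``: ``X`` has one row per window and one named
    column per feature; ``meta`` carries parent_id, site_index and label.
    Feature names are identical for every window (fixed-length contract).
    """
    if not windows:
        raise ValueError("no windows to featurize")
    config.resolved()
    first = assemble_features(windows[0], config)
    X = np.empty((len(windows), len(first)))
    X[0] = first.values
    for r, w in enumerate(windows[1:], start=1):
        fv = assemble_features(w, config)
        if fv.names != first.names:  # pragma: no cover - contract guard
            raise RuntimeError("feature-name contract violated across windows")
        X[r] = fv.values
    meta = pd.DataFrame(
        {
            "parent_id": [w.parent_id for w in windows],
            "site_index": [w.site_index for w in windows],
            "label": [w.label if w.label is not None else np.nan for w in windows],
        }
    )
    return pd.DataFrame(X, columns=first.names), meta
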