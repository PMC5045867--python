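"""Known-Motif (KM) baseline: the rule-based competitor that calls a
candidate site cleaved iff the 4-mer ending at the site matches one of the
classic dibasic patterns (X-X-K-[K/R], X-X-R-R, R-X-X-[K/R]).

It shares its matcher with the motif feature family, so the feature and
the baseline can never disagree, and it is evaluated on exactly the same
candidate windows as the ensemble for like-for-like comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import motifs
from .model import MetricsReport, compute_metrics
from .windowing import Window, WindowConfig, extract_windows, filter_candidates


@dataclass(frozen=True)
class KMRuleSet:
    """The dibasic pattern set; each pattern describes a 4-mer ending at
    the putative site with a basic residue."""

    patterns: tuple[str, ...] = motifs.KNOWN_MOTIF_PATTERNS


def km_predict(window: Window, cfg: WindowConfig = WindowConfig()) -> int:
    """1 iff any dibasic pattern matches the 4-mer ending at the site."""
    fourmer = motifs.site_fourmer(window.residues, cfg.site_offset)
    return int(motifs.matches_any(fourmer))


def km_scores(windows: Sequence[Window], cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    return np.array([km_predict(w, cfg) for w in windows], dtype=float)


def km_evaluate(windows: Sequence[Window], cfg: WindowConfig = WindowConfig()) -> MetricsReport:
    """Evaluate the baseline on labeled candidate windows."""
    truth = [w.label for w in windows]
    if any(t is None for t in truth):
        raise ValueError("KM evaluation requires labeled windows")
    return compute_metrics(truth, km_scores(windows, cfg))


def km_predict_sites(seqs, cfg: WindowConfig = WindowConfig()) -> pd.DataFrame:
    """Rule-based calls for every candidate site of ``seqs``; same output
    schema as ensemble site prediction, with probability in {0, 1}."""
    rows = []
    for seq in seqs:
        for w in filter_candidates(extract_windows(seq, cfg), cfg):
            p = float(km_predict(w, cfg))
            rows.append((seq.id, w.site_index, w.site_residue(cfg), p, int(p)))
    return pd.DataFrame(rows, columns=["seq_id", "position", "residue", "probability", "call"])
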