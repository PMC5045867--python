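# Methods

## Problem and model

The package treats proprotein-convertase cleavage as a residue-level binary
classification problem. Each residue of a precursor protein is the center
of a fixed-length sequence window; windows whose center is a candidate
(K or R, away from the termini) are featurized and classified. The design
generalizes to any per-residue binary property — the window extractor,
feature families and evaluation machinery make no cleavage-specific
assumptions; only the candidate filter (K/R centers) and the motif family
encode the dibasic-cleavage instantiation.

## Windows

* Geometry: `w_pre = 11` residues of upstream context, the putative site,
  `w_suf = 8` downstream; total length 20. Positions beyond the termini are
  filled with the pad symbol `_`, so the window on residue 1 carries 11
  pads and the window on the last residue carries 8. Coordinates are
  1-based throughout.
* Candidate filter: site residue in {K, R} and site index `i` with
  `i > d` and `i <= L - d`, `d = 4` — at least four real residues on each
  side. The boundary reading of "at least four positions away" is
  ambiguous; this package keeps a site exactly four residues from the
  C-terminus and exposes `min_terminal_distance` so users can shift it.
* Deduplication: windows sharing the 11-mer `site ± 5` (pads included in
  the key) collapse to the first-encountered representative, whose label is
  1 if any group member is labeled 1 — conflicting duplicate labels resolve
  to "cleaved". First-encounter order makes the output reproducible; the
  choice of representative beyond label resolution is arbitrary and
  documented as such.
* Whole-protein redundancy: a greedy scan keeps a sequence iff its
  ungapped best-offset identity (matches / shorter length) to every kept
  sequence is ≤ 60%. This is an explicit, deterministic approximation of
  clustering-based reduction (CD-HIT/USEARCH class); externally computed
  cluster files can be substituted.

## Feature families

Pads are feature-neutral everywhere: one-hot columns all-zero, charge 0,
PSSM rows replaced by the background distribution (zero relative entropy),
and excluded from every average. Unknown residues (`X`) one-hot to zero,
carry charge 0 and take the mean of the 20 canonical values on any scale.
Feature names (`{family}_pos{j}_{symbol}`, `{source}_seg{k}_{stat}`, …) are
a stable public contract.

* **One-hot**: full 20-letter alphabet and a 15-group reduced alphabet.
  The shipped grouping (`data/reduced15.tsv`: D/E, F/Y, I/V, K/R, S/T
  merged; others singletons) is a reconstruction — any published 15-group
  scheme can be dropped in by path.
* **Charge**: K,R → +1; D,E → −1; H, X, pads → 0. Histidine neutrality is
  configurable in code (`positional.CHARGE`).
* **PSSM**: the 20 per-position frequencies, and conservation as relative
  entropy (KL divergence, natural log) against background. The shipped
  background is the Swiss-Prot average amino-acid composition, normalized;
  a uniform background and user tables are selectable. Profiles are
  consumed as frequencies only (log-odds PSSMs are out of scope).
* **FoldIndex**: per position, `2.785·⟨H⟩ − |⟨q⟩| − 1.151` over a ±5
  neighbourhood, with Kyte–Doolittle hydropathy rescaled to [0, 1]. The
  constants come from the original unfoldability formula.
* **Contextual aggregates**: min/max/avg over `[1, X−N−1]`, `[X−N, X+N]`,
  `[X+N+1, L_w]`, `N = 4`; applied to charge (and to PSSM entropy in the
  advanced profile). A region that is empty or fully padded yields 0 with
  a warning — matrices stay dense.
* **Motifs**: the known-motif count evaluates `X-X-K-[K/R]`, `X-X-R-R`,
  `R-X-X-[K/R]` against the 4-mer *ending at* the site (cleavage is
  C-terminal to the basic pair); its range is 0–2 in practice since the
  first two patterns are mutually exclusive. The cysteine-spacer pattern
  is not printed in the source literature; the default `C-x(2,6)-C`
  (non-overlapping, counted anywhere in the window) is a documented
  reconstruction and fully configurable.
* **Global biophysical**: ExPASy-style formulas implemented in-package —
  average-mass molecular weight; isoelectric point by bisection of the
  Bjellqvist charge model on pH ∈ [0, 14] to 1e-3 (unlike the common
  bracketed search, values outside [4.05, 12] are found exactly); net
  charge at pH {3, 5, 7, 9, 11}; aromaticity; Guruprasad instability index
  `10/L · Σ DIWV` (the canonical normalization); GRAVY; aliphatic index.
  All indices are computed on the window's real residues; protein length
  refers to the whole parent. Residue masses and the DIWV table come from
  Biopython's data tables; Biopython's independent implementations serve
  as test oracles, not as the implementation.
* **Scales**: per scale, the three segment averages plus sliding averages
  of sizes {3, 5, 7}. Shipped: Kyte–Doolittle hydropathy, Hopp–Woods
  hydrophilicity, TOP-IDP disorder propensity. Further published scales
  (Atchley factors, tripeptide ASA, polarizability, …) plug in as 20-row
  TSVs; only tables whose values could be sourced exactly are shipped.

Profiles: `simple` = sequence-derived families only; `advanced` adds PSSM,
entropy (+ entropy aggregates) and the ss/acc/disorder one-hots. The simple
name set is a strict subset of the advanced one.

## Classifier and evaluation

* Committee: RBF-SVM (C = 1, gamma = 1/n_features, Platt probabilities),
  random forest (500 trees), L2 logistic regression (C = 1), all seeded,
  on z-scored features. Class call = hard majority; ranking score and the
  reported per-site probability = mean of the members' class-1
  probabilities, since a hard vote alone yields no graded confidence.
  Hyperparameters are fixed for reproducibility, not tuned.
* Selection: zero-variance features dropped, then per-feature one-way
  ANOVA F-tests with Benjamini–Hochberg step-up at q = 0.1. If nothing
  passes (pathological inputs), all varying features are kept rather than
  failing.
* Cross-validation: stratified k-fold (default 10) over windows, matching
  the usual practice for this task; scaling, unary removal and FDR
  selection are re-fit inside each training fold (verified by a leakage
  canary test). Reports carry per-fold metrics, their mean (the headline
  numbers) and pooled-prediction metrics.
* Metrics: confusion counts at probability 0.5 using the hard-vote call;
  AUC via the rank statistic with midrank ties. Ratios with zero
  denominator report 0.
* The known-motif baseline shares one matcher with the motif feature and
  is evaluated on exactly the same candidate windows as the ensemble, so
  comparisons are like-for-like.

## Synthetic corpora

The generator emulates the structure of a curated cleavage corpus, not
protein evolution: sequences are i.i.d. draws from background composition
(lengths uniform on [80, 160]; 100 sequences by default), with

* **true sites** at 2.5 per 100 residues: a canonical dibasic 4-mer with
  probability `pi_canonical = 0.9` (else a bare K/R), plus a downstream
  flank bias — each of the next 5 residues is replaced by a small/polar
  residue (G,A,S,T,N,Q,P) with probability `beta = 0.6`. The flank bias is
  the learnable non-motif signal, standing in for the real-data observation
  that discriminative features extend well beyond the motif;
* **decoys** at 1.5 per 100 residues: the same emission with
  `decoy_canonical = 0.3` and no flank bias, labeled 0 — motif look-alikes
  that stress rule-based precision;
* natural background K/R as further negatives. Defaults land the positive
  fraction among candidates near the ~16% class balance of curated sets
  (measured 13–18% across seeds).

Sites occupy exactly the candidate-eligible range [5, L−4], spaced ≥ 9
apart so edits never collide and position carries no label information.
Optional extras: label noise, near-duplicate sequences (to exercise the
redundancy filter), annotation tracks correlated with true-site flanks,
and PSSMs with sharpened (low-entropy) columns at true sites.

**The zero-signal control** (`null_config`) plants nothing: each natural
K/R candidate is independently labeled positive with probability 0.16.
Labels are then exactly independent of content. Two seemingly-null
alternatives are *not* null and were rejected: matching the decoys'
canonical-motif probability to the true sites' still leaves positives
motif-enriched relative to the natural-K/R negatives (measured CV AUC
≈ 0.85), and planting bare K/R sites is content-independent insertion,
which anti-correlates positives with local K/R density (AUC ≈ 0.47–0.59
across seeds).

What passing synthetic tests does **not** show: real proteins are not
i.i.d. background — homology, signal peptides, compositional domains and
annotation errors are absent, so absolute metric values here do not
transfer to curated corpora; only the pipeline's correctness, calibration
and the qualitative ensemble-vs-rules comparison do.

## Numerical and size choices

* Relative entropy uses natural log with `0·ln(0/pb) = 0`; a zero
  background is rejected at construction.
* PSSM rows off by ≤ 1e-3 from unit sum are renormalized; anything further
  off is a format error.
* Recovery experiments in the test suite use 40–80 sequences (roughly
  700–1,400 candidate windows) and 5–10 folds — large enough for stable
  fold means at desk scale. The null calibration averages three seeded
  corpora because a single fold-mean AUC has a standard error (~0.03)
  comparable to the ±0.05 chance band being checked.
* Known limitations: no hyperparameter search or probability calibration;
  binary labels only; window-level (not protein-level) CV folds, as is
  standard for this task, which can flatter metrics when near-duplicate
  windows survive filtering; the greedy 60% identity filter is quadratic
  in corpus size.
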