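"""Featurize a single candidate window and look at the feature families.

Shows the fixed-length named feature vector the learner consumes: one-hot
residue encodings, charge, FoldIndex disorder, motif counts, global
biophysical indices and propensity-scale aggregates.
"""

from collections import Counter

import cleavesite as cs

corpus = cs.simulate_corpus(cs.SimConfig(n_sequences=5, seed=7))
window = cs.candidate_windows(corpus)[0]

fv = cs.assemble_features(window, cs.FeatureConfig(profile="simple"))
families = Counter(name.split("_")[0] for name in fv.names)

print(f"window {window.parent_id}:{window.site_index}  {window.residues}")
print(f"total features: {len(fv)}")
for fam, n in sorted(families.items()):
    print(f"  {fam:<10} {n:>4} features")

d = dict(zip(fv.names, fv.values))
print(f"\nmotif_known_count = {d['motif_known_count']:.0f}  "
      "(dibasic patterns matching the 4-mer ending at the site)")
print(f"glob_gravy        = {d['glob_gravy']:+.3f}  (mean hydropathy of the window)")
print(f"glob_pi           = {d['glob_pi']:.2f}  (isoelectric point)")
# Every window yields the same feature names in the same order — the
# fixed-length contract that lets windows stack into a learning matrix.
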