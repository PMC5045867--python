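"""Score the candidate sites of unseen sequences with a trained model.

Trains on one simulated corpus, then emits per-site cleavage
probabilities for a fresh corpus — the per-residue annotation mode a user
would run on real precursor proteins read from FASTA.
"""

import cleavesite as cs

train = cs.simulate_corpus(cs.SimConfig(n_sequences=40, seed=1))
wins = cs.candidate_windows(train)
X, meta = cs.build_feature_matrix(wins, cs.FeatureConfig())
model = cs.fit_ensemble(X, meta["label"].astype(int).to_numpy(),
                        cs.ModelConfig(rf_trees=300, random_seed=1))

test = cs.simulate_corpus(cs.SimConfig(n_sequences=3, seed=999))
calls = cs.predict_sites(test, model, cs.FeatureConfig())

print(calls.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
called = calls[calls["call"] == 1]
print(f"\n{len(called)} of {len(calls)} candidate K/R sites called cleaved "
      "(probability > 0.5)")
# Each row is one candidate K/R residue; `probability` is the mean class-1
# probability of the three committee members, `call` its 0.5 threshold.
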