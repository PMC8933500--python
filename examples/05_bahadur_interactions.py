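"""Decompose pairwise replicator interactions with the Bahadur expansion.

For a focal RNA measured with/without two partners, log10 fold replication
is decomposed into a mean (f0), two main effects (w_j, w_k) and an
interaction (w_jk); per-term R^2 sums to 1, and a first-order sum below 1
flags a higher-order effect of the partner pair.
"""

from replinet import bahadur as bh

# additive case: partners contribute independently to log replication
additive = bh.TripletDesign.from_folds(
    "PL3", "HL1", "HL2",
    {(-1, -1): 1.0, (1, -1): 4.0, (-1, 1): 2.5, (1, 1): 10.0},
)
coef = bh.fit_bahadur(additive)
print("additive design (folds 1.0 / 4.0 / 2.5 / 10.0):")
print(f"  f0={coef.f0:.3f} w_j={coef.w_j:.3f} w_k={coef.w_k:.3f} w_jk={coef.w_jk:.3g}")
print(f"  R2_j={coef.r2_j:.3f} R2_k={coef.r2_k:.3f} R2_jk={coef.r2_jk:.3g}")
print(f"  first-order R2 sum = {coef.first_order_r2:.3f}"
      f" -> higher-order interaction present: {bh.interaction_test(coef)}")

# interactive case: replication only when both partners are present
synergy = bh.TripletDesign.from_folds(
    "PL3", "HL1", "HL2",
    {(-1, -1): 1.0, (1, -1): 1.0, (-1, 1): 1.0, (1, 1): 10.0},
)
coef = bh.fit_bahadur(synergy)
print("\nsynergistic design (replication only with both partners):")
print(f"  w_j={coef.w_j:.3f} w_k={coef.w_k:.3f} w_jk={coef.w_jk:.3f}")
print(f"  first-order R2 sum = {coef.first_order_r2:.3f}"
      f" -> higher-order interaction present: {bh.interaction_test(coef)}")
print("\nan R2 sum of 1 means the partners act additively on log replication;")
print("2/3 here says one third of the variance is the pair interaction.")
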