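"""Recover a planted signal with ranked greedy selection.

A 200 x 60 planted matrix hides 4 informative columns (plus 5 exact
duplicates of them) among noise. Univariate ranking surfaces the family,
the greedy pass prunes the duplicates at |r| >= 0.90, and the R2-vs-k
curve plateaus once the true signal is covered.
"""

from qsarkit import SplitSpec, greedy_select, make_planted_matrix, rank_univariate

pm = make_planted_matrix(n=200, p=60, k=4, n_duplicates=5, noise_sd=0.3, seed=7)
spec = SplitSpec(0.2, 11)

ranked = rank_univariate(pm.matrix, pm.targets, spec)
print("top of the univariate ranking:")
print(ranked.head(6).to_string(index=False))

trace = greedy_select(ranked, pm.matrix, pm.targets, spec, top_pool=30, max_k=12)
print(f"\nincluded (order): {trace.included_names[:8]} ...")
print(f"skipped as redundant: {[(n, b) for n, b, _ in trace.skipped]}")
print(f"R2 curve: {[(k, round(v, 3)) for k, v in trace.curve[:8]]}")
print(f"chosen k = {trace.chosen_k} -> selected {trace.selected()}")
print(
    "\nAll informative columns rank at the top; every planted duplicate is "
    "skipped with its source named as the blocker; the curve flattens once "
    "the four true columns are in."
)
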