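"""Reverse-inference decoding of a single seed region.

Generates a toy coordinate database with a planted seed-associated term,
decodes the seed, and prints the top terms with their posteriors. The
posterior P(term | activation, p) uses a fixed prior p = 0.5, so a term
carrying no evidence sits at exactly 0.5 and informative terms rise above
it; `q` is the Benjamini-Hochberg adjusted chi-square p-value.
"""

import sysdecode as sd

fx = sd.make_fixture(seed=7, n_studies=1500)
seed_name = sorted(fx.seed_masks)[0]
result = sd.decode_roi(fx.db, fx.seed_masks[seed_name], radius_mm=0.0,
                       prior=0.5, f_min=0.001, alpha=0.05)

top = result.rows.sort_values("posterior", ascending=False).head(8)
print(f"decoding seed {seed_name!r}: {result.n_active_studies} of "
      f"{result.n_studies} studies report a focus inside the seed\n")
print(f"{'term':24s} {'posterior':>9s} {'forward':>8s} {'chi2':>8s} "
      f"{'q':>9s}  significant")
for _, r in top.iterrows():
    print(f"{r.term:24s} {r.posterior:9.3f} {r.forward:8.3f} "
          f"{r.chi2:8.1f} {r.q_value:9.2e}  {bool(r.significant)}")

selected = sd.select_terms(result, k=30)
print(f"\nselected (top-30, significant): {selected}")
print("\nthe planted anatomical-style term for this seed "
      f"('anatterm_{seed_name}') should top the list with posterior well "
      "above the 0.5 prior; independent filler terms hover at ~0.5.")
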