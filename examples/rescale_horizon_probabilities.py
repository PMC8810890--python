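"""Turn literature horizon probabilities into per-slice CPT entries.

Clinical sources state risks over long horizons ("30% die of other cancers
within 25 years").  A 6-month-slice model needs the per-slice probability;
the rescaling calculus converts between the two, and odds adjustment applies
expert "r times more often" statements.
"""

from clldbn import odds_adjust, rescale_probability, rescale_probability_exact

# 30% risk over 25 years = 50 six-month slices -> one slice
p_slice = rescale_probability(0.3, k=1.0, horizon=50.0)
p_exact = rescale_probability_exact(0.3, k=1.0, horizon=50.0)
print(f"30% over 50 slices, linearized : {p_slice.p:.6f}  (0.007 at 3 d.p.)")
print(f"30% over 50 slices, const-hazard: {p_exact.p:.6f}")

# an expert says infections are 3x more frequent with autoimmune complications
base = 0.10
adjusted = odds_adjust(base, 3.0)
print(f"base infection risk {base:.2f} -> with 3x odds multiplier {adjusted:.2f}")
print("(per-slice probabilities like these populate placeholder CPT rows)")
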