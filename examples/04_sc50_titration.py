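"""Estimate SC50 from simulated yeast-display titration sequencing.

Simulates sort counts for a binder with a known SC50 of 1 uM, recovers the
value by fitting the saturable isotherm f(c) = f_max * c / (c + SC50), and
calls success against the 4 uM bar.
"""

from binderscreen import call_success, estimate_from_series, make_sort_counts

series, sorts = make_sort_counts(
    true_sc50=1.0,
    f_max=0.9,
    concentrations=[0.04, 0.2, 1.0, 5.0, 25.0, 125.0],
    depth=100_000,
    seed=4,
)
est = estimate_from_series(series, reference_sort="expr")
print(f"status    = {est.status}")
print(f"SC50      = {est.sc50:.3f} uM   (truth: 1.0 uM)")
print(f"f_max     = {est.f_max:.3f}")
print(f"success?  = {call_success(est)}  (SC50 better than 4 uM)")
# SC50 is the target concentration at which half of the expressing cells
# are collected -- a display-based affinity surrogate; designs with
# SC50 < 4 uM count as experimental successes.
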