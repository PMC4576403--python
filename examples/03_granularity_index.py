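"""The Granularity Index: definition and recovery from gated samples.

GI = hypergranular % - hypogranular % of all white blood cells, in
[-100, +100].  Samples are simulated with known latent GI values and the
index is re-estimated through the full gate-and-query path.
"""

from cytogi import autogate, gi_for_sample, granularity_index, simulate_events, template_for_gi

# Worked definition: 40 % hypergranular, 20 % hypogranular -> GI = 20 %.
print(f"granularity_index(40, 20) = {granularity_index(40.0, 20.0):.0f} %\n")

print(f"{'latent GI':>10}{'estimated GI':>14}{'hyper %':>9}{'hypo %':>8}")
for i, latent in enumerate([-45.0, -15.0, 0.0, 25.0, 50.0]):
    events = simulate_events(template_for_gi(latent), n_events=20_000, seed=10 + i)
    rec = gi_for_sample(autogate(events))
    print(f"{latent:>10.1f}{rec.gi:>14.2f}{rec.pct_hyper:>9.2f}{rec.pct_hypo:>8.2f}")

print(
    "\nThe gated estimate tracks the latent value to within a few "
    "percentage points (multinomial sampling plus gating error)."
)
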