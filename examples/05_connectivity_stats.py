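"""Composition statistics: run-length null, partner loads, Fisher's test.

The probability of N consecutive amacrine synapses uninterrupted by a
bipolar synapse is the geometric null p^N with p the per-synapse amacrine
probability.
"""

import hotspotter as h

# with a 1.6:1 amacrine:bipolar ratio, long amacrine runs are unlikely
p = h.amacrine_probability(ratio=(1.6, 1.0))
print(f"p = 1.6/2.6 = {p:.4f}")
for n in (5, 14):
    print(f"  P({n} consecutive amacrine synapses) = "
          f"{100 * h.run_probability(p, n):.1f} %")

# per-partner synapse loads under even distribution (printed study inputs)
print(f"\nsmooth cell: 126 synapses / 69 bipolar partners = "
      f"{h.mean_synapses_per_partner(126, 69):.1f} synapses per cell")
print(f"parasol:     186.3 / 40.7 = "
      f"{h.mean_synapses_per_partner(186.3, 40.7):.2f} synapses per cell")

# observed runs on a synthetic scene
dataset, truth = h.generate_paired_scene(seed=7)
smooth = next(c for c, r in truth["roles"].items() if r == "smooth")
syn = h.subset_synapses(dataset, smooth)
runs = h.find_amacrine_runs(dataset.cell(smooth), syn)
longest = max(r.length for r in runs)
print(f"\nsynthetic scene: longest amacrine run = {longest} "
      f"(null probability {100 * h.run_probability(p, longest):.2f} %), "
      f"{sum(1 for r in runs if r.length >= 5)} runs of ≥5")

# comparing bipolar-type proportions between two cells
table = [[63, 54], [96, 183]]  # DB5 vs other, by cell
print(f"\nFisher's exact (DB5 vs other input, two cells): "
      f"p = {h.fisher_exact_2x2(table):.2e} — the two cells draw differently "
      "from the shared bipolar types.")
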