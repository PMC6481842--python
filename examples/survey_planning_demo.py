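"""How many surveys or water filters guarantee detection at an occupied
site?  Cumulative detection p* = 1 - (1 - p)^n."""

from streamoccu import cumulative_curve, cumulative_detection, min_replicates

p_ves, p_edna = 0.84, 0.57  # per-survey and per-filter detection

print(f"three eDNA filters at p={p_edna}: p* = "
      f"{cumulative_detection(p_edna, 3):.2f}")
for label, p in (("VES surveys", p_ves), ("eDNA filters", p_edna)):
    n = min_replicates(p, 0.95)
    print(f"{label}: {n} replicates reach >= 95% detection confidence "
          f"(p* = {cumulative_detection(p, n):.3f})")

print("\ncumulative curve for eDNA with the single-filter interval (0.39, 0.72):")
print(cumulative_curve(p_edna, 0.39, 0.72, n_max=6).round(3).to_string(index=False))
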