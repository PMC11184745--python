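"""The complete three-stage analysis in one call.

Simulates nascent / fetal / adult contact maps (nascent relaxed, with
more trans contacts and planted compartment switches), equalizes depth,
and runs every layer: disorder metrics, compartments, TADs, loops and
TF-anchor statistics. Equivalent to `hicscape run --seed 1`.
"""

import json

import hicscape as hs

summary = hs.run_pipeline(hs.RunConfig(seed=1, outdir="scratch/pipeline_demo"))

print(json.dumps({k: summary[k] for k in
                  ("vne", "jsd", "compartment_strength", "switch_fractions",
                   "n_tads", "n_loops", "apa_score_adult", "loop_cosine")},
                 indent=2, sort_keys=True))
print()
print("Nascent shows the weakest compartmentalization (highest AB/(AA+BB))")
print("and fewest detectable loops; the planted ~18 % / ~12 % switch")
print("fractions come back from the called per-stage profiles.")
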