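"""Generate a small labeled synthetic cohort and inspect its structure.

Each visit is a 48-h recording: beat-level RR intervals, 30-s activity
counts and per-window signal-quality traces, with charging gaps and random
dropouts injected. High-severity visits (CGI-S > 4) carry a lower
deceleration-episode amplitude.
"""

import numpy as np

from physiomot import CohortConfig, clean_rr, generate_cohort, prsa_dc

cohort = generate_cohort(CohortConfig(n_patients=6, dc_effect=3.0, master_seed=1))
print(f"{len(cohort)} visits from {cohort.n_patients} patients\n")
print(f"{'visit':8s} {'label':5s} {'cgis':4s} {'dc amp (ms)':11s} {'measured DC (ms)':16s} beats")
for v in cohort.visits:
    dc, _ = prsa_dc(clean_rr(v.rr))
    print(f"{v.params.visit_id:8s} {v.label:5s} {v.params.cgis:4d} "
          f"{v.params.dc_mean:11.2f} {dc:16.3f} {len(v.rr)}")

# The measured deceleration capacity (mean phase-rectified RR response at
# heart-rate decelerations) tracks the configured episode amplitude: low
# severity visits show systematically larger DC.
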