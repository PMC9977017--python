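"""Nocturnal HRV feature block from a synthetic visit.

300-s windows shifted by 300 s are scored with 24 HRV metrics; windows
starting between 22:00 and 10:00 are aggregated to mean + variance per
metric, the 48-dimensional HRV block.
"""

from physiomot import (
    VisitParams, clean_rr, compute_window_metrics, generate_trivariate_signals,
    nocturnal_aggregate, window_rr,
)

sig = generate_trivariate_signals(
    VisitParams(patient_id="P01", visit_id="P01V1", cgis=3, seed=5)
)
rr = clean_rr(sig["rr"])
windows = window_rr(rr, win=300.0, shift=300.0)
print(f"{len(windows)} valid 300-s windows over 48 h")

metrics = []
for start, w in windows:
    m = compute_window_metrics(w)
    if m is not None:
        metrics.append((start, m))
block = nocturnal_aggregate(metrics)
print(f"nocturnal HRV block: {len(block)} features")
for name in ("nn_mean_mean", "sdnn_mean", "rmssd_mean", "pnn50_mean",
             "prsa_dc_mean", "prsa_dc_var", "sampen_mean"):
    print(f"  {name:16s} {block[name]:10.4f}")
# prsa_dc_mean is the nocturnal deceleration capacity in ms — the single
# most severity-informative feature in this pipeline.
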