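"""Compute the three performance indices from extracted landmarks.

delta locates the impedance minimum relative to the procedure midpoint
(0 = symmetric curve), DR is the percent drop from initial to minimum
impedance, and AR the percent rise from the minimum to roll-off.
"""

from rfacurve import CurveParameters, compute_indices

params = CurveParameters(
    sample_id="demo",
    t_end=100.0, t_half=50.0, t_minimum=60.0,
    Z_initial=100.0, Z_half=82.0, Z_minimum=80.0, Z_end=516.0,
    rolloff_mode="log_end",
)
idx = compute_indices(params)

print(f"delta = {idx.delta:6.1f} %  (minimum 20% past the midpoint)")
print(f"DR    = {idx.dr:6.1f} %  (impedance fell by a fifth)")
print(f"AR    = {idx.ar:6.1f} %  (roll-off impedance ~6.5x the minimum)")
print(f"dr_signed = {idx.dr_signed:.1f} %  (literal ratio value)")
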