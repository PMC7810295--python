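"""Read an RFA equipment log and extract the seven landmark parameters.

Builds a small voltage/current log (the impedance channel is derived via
Ohm's law, current in milliamps), then locates the landmark times and
impedances that summarize the ablation.
"""

from pathlib import Path
import tempfile

import numpy as np
import pandas as pd

from rfacurve import extract_parameters, read_rfa_log

# a 5-minute ablation: impedance drops 100 -> 75 ohm, then rises to roll-off
t = np.arange(0.0, 301.0)
z = np.where(
    t <= 180,
    75 + 25 * (np.exp(-1.5 * t / 180) - np.exp(-1.5)) / (1 - np.exp(-1.5)),
    75 + 330 * ((t - 180) / 120) ** 2,
)
i_ma = 900.0  # constant 0.9 A
log = pd.DataFrame({"t": t, "V": z * i_ma * 1e-3, "I": i_ma})

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "ablation_01.csv"
    log.to_csv(path, index=False)
    curve = read_rfa_log(path)  # Z = V / (I * 1e-3)
    params = extract_parameters(curve, mode="log_end")

print(f"sample            {params.sample_id}")
print(f"t_end    {params.t_end:7.1f} s   duration to first roll-off")
print(f"t_half   {params.t_half:7.1f} s   procedure midpoint")
print(f"t_min    {params.t_minimum:7.1f} s   time of the impedance minimum")
print(f"Z_init   {params.Z_initial:7.1f} ohm initial impedance")
print(f"Z_half   {params.Z_half:7.1f} ohm impedance at the midpoint")
print(f"Z_min    {params.Z_minimum:7.1f} ohm minimum impedance")
print(f"Z_end    {params.Z_end:7.1f} ohm impedance at roll-off")
# t_min > t_half here: the minimum sits after the midpoint, so the curve
# is asymmetric with a positive delta index.
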