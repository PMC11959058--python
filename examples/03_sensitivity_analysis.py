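"""Gaussian parameter-perturbation sensitivity of the sweat readout.

For each influential parameter, 100 values are drawn from a Gaussian with
SD equal to 10% of the baseline, the forward model is run per draw, and
the coefficient of variation of the simulated sweat urea is reported.
"""

from sweatkin import sensitivity_table

table = sensitivity_table(("S", "Kwu", "Cp", "Dsw", "hsg"), seed=42)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print(
    "\nCV ranks parameters by influence on the sweat readout: the active "
    "transport rate S and the water/urea dilution ratio dominate; the "
    "plasma concentration contributes weakly (passive transmission is "
    "small), and the sweat diffusivity and wall thickness are negligible "
    "in the advection-dominated steady state."
)
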