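"""Simulate the sweat urea concentration produced by a known blood value.

Runs the steady-state transport model at a post-dialysis blood urea of
6.4 mmol/L, first purely passively (S = 0) and then with an active
transport rate typical of a pre-dialysis patient, and prints the sweat
readout with its water-dilution breakdown.
"""

from sweatkin import default_parameters, simulate

params = default_parameters()

passive = simulate(6.4, params)
print(f"passive transport only (S = 0):")
print(f"  undiluted gland exit : {passive.C_sg_profile[-1]:.4f} mmol/L")
print(f"  diluted sweat readout: {passive.C_sweat:.4f} mmol/L")
print(f"  mass balance residual: {passive.mass_balance_residual:.2e}")

active = simulate(6.4, params.replace(S=0.51, u_sweat_n=2.0))
print(f"\nactive transport (S = 0.51 mmol/L/s, stimulated sweating):")
print(f"  undiluted gland exit : {active.C_sg_profile[-1]:.4f} mmol/L")
print(f"  diluted sweat readout: {active.C_sweat:.4f} mmol/L")

print(
    "\nThe passive route transmits only a few percent of blood urea to sweat "
    "(weak dermal clearance plus water dilution); the active transporter "
    "source dominates the sweat signal."
)
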