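"""Deterministic two-step fit: z and D_Tref from a table of D values.

The packaged table holds D values (decimal reduction times, minutes) of
l-carnitine thermal inactivation at eight temperatures.  The Bigelow model
log10 D_T = log10 D_Tref + (Tref - T)/z is fitted by least squares and the
coefficient t-intervals are delta-transformed onto the parameter scales.
"""

import thermoprop as tp

table = tp.load_example_table("original")
sec = tp.fit_secondary(table, t_ref=120.0)

print(f"z      = {sec.z:.1f} +/- {sec.z_ci95_half:.1f} C")
print(f"D_Tref = {sec.d_tref:.1f} +/- {sec.d_tref_ci95_half:.1f} min (Tref = 120 C)")
print()
print("z is the temperature rise that cuts the D value tenfold; D_Tref is")
print("the D value at the reference temperature.  The +/- values are 95% CI")
print("half-widths from the regression alone - they ignore the uncertainty")
print("of each input D value (see nested_mc.py for the propagated version).")
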