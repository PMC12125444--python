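"""Logan graphical analysis versus compartmental V_T.

For a reversible tracer the late part of the Logan plot is linear and its
slope estimates the total distribution volume without fitting the full
compartment model. Here both estimators run on the same noiseless synthetic
subject, so the difference is pure method bias (finite t*, blood-volume
signal), not noise.
"""

import petkin as pk
from petkin.synthetic import InputModel, generate_input

schedule = pk.parse_frame_schedule(pk.DEFAULT_PROTOCOL)
ifs = generate_input(InputModel(), schedule)

truth = pk.TwoTissueParams(vb=0.038, K1=0.271, k2=0.190, k3=0.039, k4=0.070, delay=3.766)
tac = pk.solve_2tcm(truth, ifs, schedule, label="medial_temporal")

vt_true = pk.compute_vt(truth)
fit = pk.fit_2tcm(tac, ifs)
logan = pk.logan_vt(tac, ifs, tstar=20.0)

print(f"compartmental truth V_T : {vt_true:.4f} mL/cm^3")
print(f"2TCM fitted V_T         : {fit.vt:.4f} mL/cm^3")
print(f"Logan V_T (t*=20 min)   : {logan.vt:.4f} mL/cm^3 "
      f"({logan.n_points} points, R^2={logan.r_squared:.5f})")
print(f"Logan intercept         : {logan.intercept:.3f} min")
print()
print("The Logan slope sits within a few percent of the compartmental value;")
print("the residual offset is the expected pre-equilibrium bias plus the")
print("vb-weighted blood signal that the graphical method does not model.")
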