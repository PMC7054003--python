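"""From the diffusive search to the five kinetic pathways.

Evaluates the site-resolved mean first-passage times, the pathway
probabilities (forward step, backward step, leading/trailing stomps,
termination), and the mean binding times at zero load and near stall.
"""

import numpy as np

from myovstep import KineticRates, LoadForce, MotorParams, StepModel

params = MotorParams()
rates = KineticRates()

for F in (0.0, 1.8):
    model = StepModel(params, rates, LoadForce(F=F))
    sp, pp, bt = model.passage, model.pathways, model.times
    best = sp.n[np.argmin(sp.tfp)]
    print(f"backward load F = {F} pN")
    print(f"  fastest site n = {best} (z = {best * 36 / 13:.0f} nm), "
          f"tfp = {sp.tfp.min():.3f} ms; diffusion-limited "
          f"t_diff = {sp.t_diff:.3f} ms")
    print(f"  P(forward) = {pp.Pf:.3f}  P(backward) = {pp.Pb:.2e}  "
          f"P(trailing stomp) = {pp.PTs:.2e}  "
          f"P(leading stomp) = {pp.PLs:.3f}  P(termination) = {pp.Pt:.4f}")
    print(f"  step ratio Pb/Pf = {pp.step_ratio:.3g}")
    print(f"  binding times: trailing tT = {bt.tT:.2f} ms "
          f"(hydrolysis floor {rates.th:.2f} ms), leading tL = {bt.tL:.2f} ms")
    print()

print("The trailing binding time jumps by an order of magnitude near")
print("stall: load rotates the search toward backward sites, where the")
print("post-recovery-stroke head orientation penalizes binding (b = 0.045),")
print("so many diffusive excursions are needed before capture.")
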