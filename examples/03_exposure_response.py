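"""The sedation exposure-response curve and its clinical anchor points.

Uses the published logistic coefficients (intercept 0.27, slope 0.01 per
pg/mL) linking the 45-min Cmax to the probability of reaching a Ramsay
sedation score >= 3.
"""

import dexpop as dp

er = dp.PUBLISHED_ER
print(f"logit P(sedation) = {er.intercept} + {er.slope} x Cmax[pg/mL]")
for conc in (0, 50, 100, 180, 250):
    print(f"  Cmax {conc:3d} pg/mL -> P(RSS>=3 within 45 min) = "
          f"{dp.prob_at(er, conc):.3f}")
print(f"Cmax for 80% sedation probability: {dp.conc_for_prob(er, 0.8):6.1f} pg/mL")
print(f"Cmax for 90% sedation probability: {dp.conc_for_prob(er, 0.9):6.1f} pg/mL")
print("About 100 and 180-190 pg/mL: the exposure targets used to judge "
      "the dosing simulations.")
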