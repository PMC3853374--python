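"""The clinical scalar formulas: BSA, estimated GFR, and plasma AUC.

Body surface area (Mosteller) determines the cisplatin dose; Cockcroft-Gault
creatinine clearance tracks nephrotoxicity before and after treatment; the
trapezoidal rule integrates sampled plasma concentrations into systemic
exposure (AUC).
"""

import periquant as pq

bsa = pq.mosteller_bsa(height_cm=180, weight_kg=80)
print(f"Mosteller BSA (180 cm, 80 kg): {bsa:.2f} m^2")

male = pq.PatientVitals(age=40, sex="male", height=180, weight=72, serum_creatinine=1.0)
female = pq.PatientVitals(age=40, sex="female", height=165, weight=72, serum_creatinine=1.0)
print(f"Cockcroft-Gault, male 40 y / 72 kg / SCr 1.0 : {pq.cockcroft_gault_gfr(male):6.1f} cc/min")
print(f"Cockcroft-Gault, same vitals, female         : {pq.cockcroft_gault_gfr(female):6.1f} cc/min")

# intraoperative samples at 10, 30 and 60 minutes
series = pq.PlasmaSeries(times=(10, 30, 60), concentrations=(3.2, 2.4, 1.5))
print(f"plasma AUC (10-60 min): {pq.trapezoid_auc(series):.1f} mg.min/L")
# The AUC covers only the sampled span; no extrapolation to t=0 or infinity.
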