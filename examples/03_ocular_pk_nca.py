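"""Predict vitreal half-lives from molecule size and run NCA on a simulated
destructive-sampling study.

The anterior-route model scales half-life with hydrodynamic radius
(r_h ∝ MW^(1/3)); anchoring the ranibizumab (48 kDa) prediction at 3.8 days
fixes the scale for the other agents. The NCA section then recovers PK
parameters from a simulated 7-animals-per-day vitreous study.
"""

import numpy as np

from ocuvegf import default_study_config, nca, predict_vitreal_half_life
from ocuvegf.config import ASSAY_LLOQ_UG_PER_ML
from ocuvegf.pk import profile_from_frame
from ocuvegf.synthetic import SyntheticStudySpec, generate_vitreous_pk_dataset

config = default_study_config()

print("size-scaled half-life predictions (anchor: ranibizumab 3.8 d):")
for agent in config.agents:
    t = predict_vitreal_half_life(agent, config.geometry, anchor=(48.0, 3.8))
    print(f"  {agent.name:<13s} MW {agent.molecular_weight:5.0f} kDa -> "
          f"t1/2 = {t:.1f} d")

spec = SyntheticStudySpec(seed=21)
data = generate_vitreous_pk_dataset(spec)
print("\nNCA on simulated destructive-sampling profiles "
      f"({spec.animals_per_group} animals/day, {spec.noise_cv_pk:.0%} CV):")
hdr = f"  {'agent':<13s}{'AUC':>8s}{'C_0':>8s}{'CL':>7s}{'V_ss':>7s}{'t1/2':>7s}"
print(hdr)
for agent in config.agents:
    prof = profile_from_frame(data, agent.name,
                              lloq=ASSAY_LLOQ_UG_PER_ML[agent.name])
    r = nca(prof, dose_ug=agent.dose_mass)
    print(f"  {agent.name:<13s}{r.auc:8.0f}{r.c0:8.0f}{r.cl:7.2f}"
          f"{r.vss:7.2f}{r.t_half:7.2f}")
print("\nUnits: AUC day*ug/mL, C_0 ug/mL, CL mL/day, V_ss mL, t1/2 days.")
print("Recovered half-lives should sit near the generating 5.63/3.10/3.15 d.")
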