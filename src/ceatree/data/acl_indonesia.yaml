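schema_version: 1
parameters:
- name: p_meniscus_aclr
  kind: probability
  base: 0.08
  low: 0.04
  high: 0.12
  dist:
    family: beta
    mean: 0.08
    se: 0.008
  note: meniscus surgery after early ACLR; assumed (trial-informed order of magnitude)
- name: p_revision_aclr
  kind: probability
  base: 0.05
  low: 0.02
  high: 0.08
  dist:
    family: beta
    mean: 0.05
    se: 0.005000000000000001
  note: ACL revision after early ACLR; assumed
- name: p_other_aclr
  kind: probability
  base: 0.05
  low: 0.0
  high: 0.1
  dist:
    family: beta
    mean: 0.05
    se: 0.005000000000000001
  note: other surgery after early ACLR; clinician-experience branch, assumed
- name: p_arthroscopy_conserv
  kind: probability
  base: 0.1
  low: 0.05
  high: 0.15
  dist:
    family: beta
    mean: 0.1
    se: 0.010000000000000002
  note: meniscus arthroscopy without ACLR under conservative care; assumed
- name: p_delayed_aclr
  kind: probability
  base: 0.41
  low: 0.3
  high: 0.5
  dist:
    family: beta
    mean: 0.41
    se: 0.041
  note: crossover to delayed ACLR over 18 months
- name: u_stable_aclr
  kind: utility
  base: 0.86
  low: 0.84
  high: 0.88
  dist:
    family: beta
    mean: 0.86
    se: 0.08600000000000001
  note: EQ-5D-3L utility, stable knee after early ACLR
- name: u_stable_conserv
  kind: utility
  base: 0.81
  low: 0.79
  high: 0.83
  dist:
    family: beta
    mean: 0.81
    se: 0.08100000000000002
  note: EQ-5D-3L utility, stable knee after conservative treatment
- name: u_baseline
  kind: utility
  base: 0.61
  low: 0.55
  high: 0.67
  dist:
    family: beta
    mean: 0.61
    se: 0.061
  note: pre-treatment utility; context value, not used in terminal payoffs
- name: du_reop_aclr
  kind: utility
  base: 0.0
  low: 0.0
  high: 0.05
  dist:
    family: fixed
  note: utility decrement on re-operation branches (early-ACLR arm); calibrated residual
- name: du_reop_conserv
  kind: utility
  base: 0.0
  low: 0.0
  high: 0.05
  dist:
    family: fixed
  note: utility decrement on re-operation branches (conservative arm); calibrated residual
- name: c_aclr_direct
  kind: cost
  base: 2853.0
  low: 2282.4
  high: 3423.6
  dist:
    family: gamma
    mean: 2853.0
    se: 570.6
  note: direct cost of one ACL reconstruction
- name: c_meniscus_surgery
  kind: cost
  base: 800.0
  low: 640.0
  high: 960.0
  dist:
    family: gamma
    mean: 800.0
    se: 160.0
  note: meniscus surgery / arthroscopy cost; assumed
- name: c_other_surgery
  kind: cost
  base: 500.0
  low: 400.0
  high: 600.0
  dist:
    family: gamma
    mean: 500.0
    se: 100.0
  note: other-surgery cost; assumed
- name: c_rehab_visit
  kind: cost
  base: 15.0
  low: 12.0
  high: 18.0
  dist:
    family: gamma
    mean: 15.0
    se: 3.0
  note: per-visit physiotherapy cost; assumed
- name: n_rehab_visits_week
  kind: count
  base: 2.0
  low: 2.0
  high: 2.0
  dist:
    family: fixed
  note: post-operative rehabilitation visits per week
- name: n_rehab_weeks
  kind: count
  base: 36.0
  low: 36.0
  high: 36.0
  dist:
    family: fixed
  note: post-operative rehabilitation duration in weeks
- name: c_base_aclr
  kind: cost
  base: 101.34999999999945
  low: 81.07999999999957
  high: 121.61999999999934
  dist:
    family: gamma
    mean: 101.34999999999945
    se: 20.269999999999893
  note: residual per-patient arm cost (indirect costs etc.); calibrated
- name: c_base_conserv
  kind: cost
  base: 1597.4700000003631
  low: 1277.9760000002907
  high: 1916.9640000004356
  dist:
    family: gamma
    mean: 1597.4700000003631
    se: 319.4940000000727
  note: residual per-patient arm cost (rehabilitation + indirect); calibrated
tree:
  label: ACL injury treatment
  strategies:
  - label: Early ACLR
    kind: chance
    branches:
    - prob: p_meniscus_aclr
      node:
        label: Meniscus surgery
        kind: terminal
        branches: []
        cost: c_base_aclr + c_aclr_direct + c_rehab_visit * n_rehab_visits_week * n_rehab_weeks + c_meniscus_surgery
        effect: u_stable_aclr - du_reop_aclr
    - prob: p_revision_aclr
      node:
        label: ACL revision
        kind: terminal
        branches: []
        cost: c_base_aclr + c_aclr_direct + c_rehab_visit * n_rehab_visits_week * n_rehab_weeks + c_aclr_direct
        effect: u_stable_aclr - du_reop_aclr
    - prob: p_other_aclr
      node:
        label: Other surgery
        kind: terminal
        branches: []
        cost: c_base_aclr + c_aclr_direct + c_rehab_visit * n_rehab_visits_week * n_rehab_weeks + c_other_surgery
        effect: u_stable_aclr - du_reop_aclr
    - prob: complement
      node:
        label: No further surgery
        kind: terminal
        branches: []
        cost: c_base_aclr + c_aclr_direct + c_rehab_visit * n_rehab_visits_week * n_rehab_weeks
        effect: u_stable_aclr
  - label: Conservative treatment
    kind: chance
    branches:
    - prob: p_arthroscopy_conserv
      node:
        label: Meniscus arthroscopy without ACLR
        kind: terminal
        branches: []
        cost: c_base_conserv + c_meniscus_surgery
        effect: u_stable_conserv - du_reop_conserv
    - prob: p_delayed_aclr
      node:
        label: Delayed ACLR
        kind: terminal
        branches: []
        cost: c_base_conserv + c_aclr_direct + c_rehab_visit * n_rehab_visits_week * n_rehab_weeks
        effect: u_stable_conserv - du_reop_conserv
    - prob: complement
      node:
        label: Stable with rehabilitation alone
        kind: terminal
        branches: []
        cost: c_base_conserv
        effect: u_stable_conserv
settings:
  wtp: 12876.0
  discount_rate: 0.03
  horizon_months: 18.0
  effectiveness_mode: utility_at_horizon
  psa_draws: 5000
  seed: 2022
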