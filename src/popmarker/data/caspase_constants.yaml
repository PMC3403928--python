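# Kinetic constants of the bundled caspase-cascade single-cell model.
#
# Units: molecule numbers per cell and minutes; bimolecular constants in
# 1/(molecule*min), first-order constants in 1/min, synthesis rates in
# molecules/min.  The model converts to hours at the simulation interface.
#
# Naming: the four synthesis rates keep the indices used in the population
# study (km8 = IAP synthesis, km10 = C3 synthesis, km9 = C8 synthesis,
# km12 = CARP synthesis; "km" = k-minus) with the paired first-order
# degradations k8/k9/k10/k12.  The mapping of km9/km12 onto C8 vs CARP is
# fixed by the turnover ratios reproducing the resting copy numbers
# (C8 1.3e5, C3 2.1e4, IAP 4e4, CARP 4e4); it is an assumption in the
# sense that only those resting levels, not the index labels, pin it down.
#
# Transcribed from the original single-cell model publication; validated
# against the population-level classification results it was used for
# (see docs/methods.md, "Kinetic constants").
constants:
  k_act_c8:
    value: 5.8e-5
    unit: 1/(molecule*min)
    note: activation of C8 by C3a (feedback loop)
  k_act_c3:
    value: 1.0e-5
    unit: 1/(molecule*min)
    note: activation of C3 by C8a (initiator -> effector)
  k_bind_c3a_iap:
    value: 5.0e-4
    unit: 1/(molecule*min)
    note: association of C3a with IAP
  k_unbind_c3a_iap:
    value: 0.21
    unit: 1/min
    note: dissociation of the C3a~IAP complex
  k_degbind_iap:
    value: 3.0e-4
    unit: 1/(molecule*min)
    note: C3a-induced degradation of IAP
  k_bind_c8a_carp:
    value: 5.0e-4
    unit: 1/(molecule*min)
    note: association of C8a with CARP
  k_unbind_c8a_carp:
    value: 0.21
    unit: 1/min
    note: dissociation of the C8a~CARP complex
  k_deg_c8a:
    value: 5.8e-3
    unit: 1/min
    note: degradation of free C8a
  k_deg_c3a:
    value: 1.16e-2
    unit: 1/min
    note: degradation of free C3a
  k_deg_c3a_iap:
    value: 1.73e-2
    unit: 1/min
    note: degradation of the C3a~IAP complex
  k_deg_c8a_carp:
    value: 1.16e-2
    unit: 1/min
    note: degradation of the C8a~CARP complex
  k8:
    value: 1.16e-2
    unit: 1/min
    note: degradation of IAP (pairs with km8)
  km8:
    value: 464.0
    unit: molecules/min
    note: synthesis of IAP (heterogeneous in the case study)
  k9:
    value: 3.9e-3
    unit: 1/min
    note: degradation of C8 (pairs with km9)
  km9:
    value: 507.0
    unit: molecules/min
    note: synthesis of C8 (heterogeneous in the case study)
  k10:
    value: 3.9e-3
    unit: 1/min
    note: degradation of C3 (pairs with km10)
  km10:
    value: 81.9
    unit: molecules/min
    note: synthesis of C3 (heterogeneous in the case study)
  k12:
    value: 1.0e-3
    unit: 1/min
    note: degradation of CARP (pairs with km12)
  km12:
    value: 40.0
    unit: molecules/min
    note: synthesis of CARP (heterogeneous in the case study)
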