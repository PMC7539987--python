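# xcquench 0.1.0 kinetic model
# C. vulgaris intact-cell defaults: light-driven xanthophyll cycling
# plus qE/qZ/qI quenching couplings.  De-epoxidation on the native
# membrane is faster than in the reconstituted assay; epoxidation is
# slow enough that <15% of zeaxanthin reconverts in a 5-min dark spell.
k_de1 = 0.07
k_de2 = 0.07
k_ep = 0.028
dtt_inhibition = 0.0
species_label = 'C. vulgaris'
ph_profile.ph_opt = 5.1
ph_profile.slope_acid = 0.35
ph_profile.slope_alkaline = 0.45
ph_profile.acid_offset = 1.0
ph_profile.species_label = 'C. vulgaris'
light_to_ph.ph_dark = 7.0
light_to_ph.ph_span = 2.0
light_to_ph.half_sat = 1000.0
light_to_ph.tau = 30.0
q_params.qe_max = 2.4
q_params.qe_tau_ind = 45.0
q_params.qe_tau_rel = 90.0
q_params.qe_ph_half = 6.8
q_params.qe_ph_slope = 0.1
q_params.qe_zea_half = 0.25
q_params.qe_zea_basal = 0.03
q_params.qz_max = 4.0
q_params.qz_zea_half = 0.8
q_params.qz_tau_ind = 600.0
q_params.qz_tau_rel = 1800.0
q_params.qi_max = 0.6
q_params.qi_irr_half = 500.0
q_params.qi_tau_ind = 1200.0
q_params.qi_tau_rel = 3600.0
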