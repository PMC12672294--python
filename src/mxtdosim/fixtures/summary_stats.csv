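name,value
g_ratio_water_abs_mean,0.85
g_ratio_water_abs_sd,0.1
g_water_diff_mean,0.05
g_water_diff_sd,0.05
g_abs_diff_mean,0.07
g_abs_diff_sd,0.05
g_abs_diff_max,0.12
g_abs_diff_argmax_r_cm,4.8
g_abs_diff_at_2cm,0.09
g_abs_diff_at_3cm,0.1
g_abs_diff_at_4cm,0.11
g_abs_diff_at_5cm,0.1
xr_ebt_diff_at_2cm,0.03
xr_ebt_diff_at_3cm,-0.01
xr_ebt_diff_at_4cm,0.02
xr_ebt_diff_at_5cm,0.04
azimuthal_max_ratio,1.06
azimuthal_argmax_phi_deg,150.0
f_ratio_max,1.26
f_ratio_argmax_r_cm,4.2
f_ratio_argmax_theta_deg,50.0
f_ratio_min,0.84
f_ratio_argmin_r_cm,3.6
f_ratio_argmin_theta_deg,20.0
type_b_quadrature_percent,12.02
type_a_quadrature_percent,0.04
total_uncertainty_printed_percent,12.06
lambda_abs_cgy_h_ua,1104.28
lambda_water_cgy_h_ua,1344.14
cf_at_1cm,1.23
cf_at_5cm,0.85
air_kerma_strength_gy_cm2_min,108.1
mc_combined_uncertainty_1cm_percent,5.12
mc_combined_uncertainty_3cm_percent,4.36
mc_global_mean_relative_error_percent,0.07
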