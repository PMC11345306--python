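feature_id,display_name,pathological_limb_feature,p_reported,mean_healthy,sd_healthy,mean_hd,sd_hd,n_healthy,n_hd
extension_r,Extension,1,3.1e-3,2.03,0.74,2.91,1.10,30,14
step_length_r,Step length,1,3.3e-3,0.03,0.01,0.06,0.03,30,14
max_acc_amp_r,MaxAccAmp,1,2.2e-3,2.16,1.07,3.41,1.31,30,14
ventral_acceleration_r,Peak vertical force,1,3.8e-3,144.39,69.52,230.61,107.51,30,14
max_gyr_amp_r,MaxGyrAmp,1,6.7e-3,0.57,0.25,0.83,0.32,30,14
std_acc_r,Standard deviation,1,5.2e-3,0.43,0.16,0.61,0.22,30,14
sym_ext_fl_hr,Extension Symmetry Femur L - Humerus R,0,1.0e-2,12.06,4.41,16.86,7.07,30,14
sym_maxacc_fr_fl,MaxAccAmp Symmetry Femur R - Femur L,0,4.4e-2,3.95,1.25,5.19,2.06,30,14
sym_maxacc_fr_hl,MaxAccAmp Symmetry Femur R - Humerus L,0,9.9e-2,10.40,4.4,14.34,4.42,30,14
sym_maxacc_fl_hr,MaxAccAmp Symmetry Femur L - Humerus R,0,1.4e-2,9.58,3.61,13.02,4.48,30,14
sym_normstep_fr_hl,Normalised step length Symmetry Femur R - Humerus L,0,1.0e-2,3.26,2.72,8.60,9.93,30,14
sym_step_fr_hl,Step length Symmetry Femur R - Humerus L,0,1.0e-2,3.26,2.72,8.6,9.93,30,14
sym_pr_lumbar,Symmetry PR Lumbar,0,1.1e-2,2.21,0.90,2.98,1.13,30,14
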