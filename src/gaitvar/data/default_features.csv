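feature_id,display_name,unit,exclusion_category,laterality,symmetry_pair
extension_r,Extension (right),deg,none,right,extension_l
extension_l,Extension (left),deg,none,left,extension_r
step_length_r,Step length (right),m,step_length,right,step_length_l
step_length_l,Step length (left),m,step_length,left,step_length_r
max_acc_amp_r,MaxAccAmp (right),m/s^2,none,right,max_acc_amp_l
max_acc_amp_l,MaxAccAmp (left),m/s^2,none,left,max_acc_amp_r
ventral_acceleration_r,Ventral acceleration (right),m/s^2,energy,right,ventral_acceleration_l
ventral_acceleration_l,Ventral acceleration (left),m/s^2,energy,left,ventral_acceleration_r
max_gyr_amp_r,MaxGyrAmp (right),rad/s,none,right,max_gyr_amp_l
max_gyr_amp_l,MaxGyrAmp (left),rad/s,none,left,max_gyr_amp_r
std_acc_r,Standard deviation (right),m/s^2,none,right,std_acc_l
std_acc_l,Standard deviation (left),m/s^2,none,left,std_acc_r
sym_ext_fl_hr,Extension Symmetry Femur L - Humerus R,%,none,left,sym_ext_fr_hl
sym_ext_fr_hl,Extension Symmetry Femur R - Humerus L,%,none,right,sym_ext_fl_hr
sym_maxacc_fr_fl,MaxAccAmp Symmetry Femur R - Femur L,%,none,right,sym_maxacc_fl_fr
sym_maxacc_fl_fr,MaxAccAmp Symmetry Femur L - Femur R,%,none,left,sym_maxacc_fr_fl
sym_maxacc_fr_hl,MaxAccAmp Symmetry Femur R - Humerus L,%,none,right,sym_maxacc_fl_hr
sym_maxacc_fl_hr,MaxAccAmp Symmetry Femur L - Humerus R,%,none,left,sym_maxacc_fr_hl
sym_normstep_fr_hl,Normalised step length Symmetry Femur R - Humerus L,%,none,right,sym_normstep_fl_hr
sym_normstep_fl_hr,Normalised step length Symmetry Femur L - Humerus R,%,none,left,sym_normstep_fr_hl
sym_step_fr_hl,Step length Symmetry Femur R - Humerus L,%,none,right,sym_step_fl_hr
sym_step_fl_hr,Step length Symmetry Femur L - Humerus R,%,none,left,sym_step_fr_hl
sym_pr_lumbar,Symmetry PR Lumbar,%,none,axial,
withers_height,Withers height,m,withers,axial,
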