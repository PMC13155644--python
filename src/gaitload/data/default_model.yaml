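# Reduced sagittal-plane musculoskeletal model, version 1.
#
# Sign conventions: hip flexion +, knee extension +, ankle plantarflexion +.
# Moment arms in metres (signed per the conventions above), f_max in newtons,
# c_knee = dimensionless axial projection of muscle force onto the tibia's
# longitudinal axis (0 for muscles that do not span the knee).
# theta_ref in degrees: joint angles at which normalized fiber length = 1.
version: 1
reserve_weight: 1000.0
fl_width: 0.45
passive_strain: 0.6
passive_exp_k: 10.0
theta_ref: {hip: 10.0, knee: 10.0, ankle: 0.0}
muscles:
  gluteals:
    f_max: 4000.0
    moment_arms: {hip: -0.060}
    l_opt: 0.15
    c_knee: 0.0
  iliopsoas:
    f_max: 2500.0
    moment_arms: {hip: 0.050}
    l_opt: 0.12
    c_knee: 0.0
  hamstrings:
    f_max: 3500.0
    moment_arms: {hip: -0.060, knee: -0.035}
    l_opt: 0.11
    c_knee: 0.30
  rectus_femoris:
    f_max: 1800.0
    moment_arms: {hip: 0.040, knee: 0.045}
    l_opt: 0.09
    c_knee: 0.60
  vasti:
    f_max: 8000.0
    moment_arms: {knee: 0.045}
    l_opt: 0.10
    c_knee: 0.70
  gastrocnemius:
    f_max: 2800.0
    moment_arms: {knee: -0.020, ankle: 0.050}
    l_opt: 0.06
    c_knee: 0.90
  soleus:
    f_max: 5200.0
    moment_arms: {ankle: 0.040}
    l_opt: 0.05
    c_knee: 0.0
  tibialis_anterior:
    f_max: 1500.0
    moment_arms: {ankle: -0.035}
    l_opt: 0.07
    c_knee: 0.0
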