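# Published regression equations for daily enteric CH4 emission (L/day) and
# methane conversion factor (MCF, J per 100 J of gross energy intake) in
# Holstein lactating cows, fitted on an n = 121 indirect-calorimetry panel.
# Covariate keys: LW   live weight (kg)
#                 DMI  dry matter intake (kg/day)
#                 ECM  energy-corrected milk (kg/day)
#                 CH4CO2  breath CH4/CO2 volume ratio (L/L)
# Coefficients are stored at printed precision and never re-derived.
equations:
  eq1:
    response: CH4_L_per_day
    intercept: -397.0
    intercept_se: 37.4
    coefficients: {LW: 0.317, DMI: 13.3, ECM: 3.14, CH4CO2: 4343.0}
    coefficient_se: {LW: 0.0557, DMI: 1.53, ECM: 0.816, CH4CO2: 258.1}
    adj_r2: 0.898
    rmse: 31.9
  eq2:
    response: CH4_L_per_day
    intercept: -507.0
    intercept_se: 45.0
    coefficients: {LW: 0.536, ECM: 8.76, CH4CO2: 5029.0}
    coefficient_se: {LW: 0.0635, ECM: 0.630, CH4CO2: 313.8}
    adj_r2: 0.833
    rmse: 40.8
  eq3:
    response: CH4_L_per_day
    intercept: -346.0
    intercept_se: 37.0
    coefficients: {LW: 0.277, DMI: 18.0, CH4CO2: 4040.0}
    coefficient_se: {LW: 0.0579, DMI: 0.98, CH4CO2: 259.8}
    adj_r2: 0.886
    rmse: 33.8
  eq4:
    response: CH4_L_per_day
    intercept: -248.0
    intercept_se: 41.4
    coefficients: {ECM: 10.5, CH4CO2: 5169.0}
    coefficient_se: {ECM: 0.75, CH4CO2: 395.7}
    adj_r2: 0.734
    rmse: 51.5
  eq5:
    response: CH4_L_per_day
    intercept: -219.0
    intercept_se: 27.9
    coefficients: {DMI: 20.4, CH4CO2: 3991.0}
    coefficient_se: {DMI: 0.92, CH4CO2: 282.7}
    adj_r2: 0.864
    rmse: 36.8
  eq6:
    response: CH4_L_per_day
    intercept: 230.0
    intercept_se: 30.5
    coefficients: {ECM: 9.54}
    coefficient_se: {ECM: 1.168}
    adj_r2: 0.354
    rmse: 80.2
  eq7:
    response: CH4_L_per_day
    intercept: 109.0
    intercept_se: 25.4
    coefficients: {DMI: 21.7}
    coefficient_se: {DMI: 1.49}
    adj_r2: 0.638
    rmse: 60.1
  eq8:
    response: MCF_J_per_100J
    intercept: 0.01
    intercept_se: 0.005
    coefficients: {LW: 0.00004, DMI: -0.002, ECM: 0.0003, CH4CO2: 60.7}
    coefficient_se: {LW: 0.000008, DMI: 0.0002, ECM: 0.00011, CH4CO2: 3.55}
    adj_r2: 0.766
    rmse: 0.440
  eq9:
    response: MCF_J_per_100J
    intercept: 1.44
    intercept_se: 0.493
    coefficients: {LW: 0.00352, DMI: -0.148, CH4CO2: 57.9}
    coefficient_se: {LW: 0.000772, DMI: 0.0131, CH4CO2: 3.46}
    adj_r2: 0.755
    rmse: 0.450
  eq10:
    response: MCF_J_per_100J
    intercept: 2.91
    intercept_se: 0.460
    coefficients: {ECM: -0.0498, CH4CO2: 51.0}
    coefficient_se: {ECM: 0.00836, CH4CO2: 4.39}
    adj_r2: 0.604
    rmse: 0.572
  eq11:
    response: MCF_J_per_100J
    intercept: 3.06
    intercept_se: 0.370
    coefficients: {DMI: -0.118, CH4CO2: 57.3}
    coefficient_se: {DMI: 0.0121, CH4CO2: 3.74}
    adj_r2: 0.713
    rmse: 0.487
  eq12:
    response: MCF_J_per_100J
    intercept: 1.43
    intercept_se: 0.440
    coefficients: {CH4CO2: 53.5}
    coefficient_se: {CH4CO2: 4.96}
    adj_r2: 0.490
    rmse: 0.649
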