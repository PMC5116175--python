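parameter,description,population_mean,iiv,bootstrap_value,ci_2.5,ci_97.5
V,Volume of distribution for the central compartment (mL),326627,1.072,260011.65,169213.19,369548.19
Cl,Central clearance (mL/h),21109.2,0.184,19214.724,16224.881,22463.998
V2,Volume of distribution for the peripheral compartment (mL),676758,0.232,721665.925,67400.388,835445.28
Cl2,Clearance between the central and the peripheral compartment (mL/h),12550.5,0.710,16958.522,11499.469,24340.243
CLmilk,Clearance from the central compartment to the milk (mL/h),882.461,0.121,816.285,686.264,957.191
Ka,Absorption rate constant after subcutaneous injection (1/h),0.295,6.255,0.938,0.327,2.318
sigma_plasma,Proportional residual error for plasma concentrations,0.485,NA,0.484,0.419,0.549
sigma_milk,Proportional residual error for cumulative milk amounts,0.0234,NA,0.0228,0.0157,0.0279
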