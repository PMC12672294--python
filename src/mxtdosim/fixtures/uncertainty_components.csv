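name,value_percent,type,source
repeated film measurements,0.04,A,repeated EBT3 readings at the reference point
film calibration (6 MV beam),0.5,B,residuals of the dose-netOD cubic fit
film response at low energy,11.0,B,literature value for EBT3 under kV polyenergetic beams
medium conversion factor (CF_M),4.72,B,RMSE of the ABS-to-water depth-dose conversion
geometric setup,0.98,B,±1 mm positioning tolerance
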