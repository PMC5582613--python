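hepatocyte_sample,dose_uM,time_h,compound,concentration_uM
HL-1,1,24,MeIQx,0.05
HL-1,1,24,MeIQx-N2-Gl,0.02
HL-1,1,24,MeIQx-N2-SO3H,0.13
HL-1,1,24,oxo-MeIQx,0.05
HL-1,1,24,C-Hydroxy-MeIQx,0.41
HL-1,1,24,HON-MeIQx-N2-Gl,0.08
HL-1,10,24,MeIQx,1.4
HL-1,10,24,MeIQx-N2-Gl,0.9
HL-1,10,24,MeIQx-N2-SO3H,2.3
HL-1,10,24,oxo-MeIQx,1.2
HL-1,10,24,C-Hydroxy-MeIQx,0.9
HL-1,10,24,HON-MeIQx-N2-Gl,0.8
HL-1,50,24,MeIQx,29
HL-1,50,24,MeIQx-N2-Gl,1
HL-1,50,24,MeIQx-N2-SO3H,6
HL-1,50,24,oxo-MeIQx,6.5
HL-1,50,24,C-Hydroxy-MeIQx,1.5
HL-1,50,24,HON-MeIQx-N2-Gl,1
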