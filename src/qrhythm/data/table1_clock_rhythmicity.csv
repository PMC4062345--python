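gene,acrophase_h,p_ns
arntl1,14.6,0.41
arntl2,16.1,0.01
clock,9.04,0.06
npas2,4.36,0.08
cry1a,15.6,0.62
cry1b,19.3,0.63
cry-dash,10.3,0.99
cry2,1.04,0.05
cry3,2.53,0.27
per1,21.2,0.88
per2a,17.5,0.07
per2b,21.4,0.83
tim,6.33,0.37
nr1d1,6.01,0.21
nr1d2a,9.01,0.01
nr1d2b,19.3,0.51
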