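d0	s02	d0_cm	s02_cm
10.1980849990432	1.02687969520704	10.1980849990431	1.02687969520704
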