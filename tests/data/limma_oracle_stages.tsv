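	stage
s00	control
s01	control
s02	control
s03	control
s04	I
s05	I
s06	I
s07	I
s08	II
s09	II
s10	II
s11	II
s12	III
s13	III
s14	III
s15	III
s16	IV
s17	IV
s18	IV
s19	IV
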