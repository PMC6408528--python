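# Acoustic and thermal material constants (water at 27 C; bulk gold).
# Units: rho g/cm^3 | beta 1/K | v m/s | cp J/K/kg | gamma - | z N.s/m^3 | alpha_th m^2/s
name	rho	beta	v	cp	gamma	z	alpha_th
water	1	210e-6	1500	4180	0.11	1.5e6	0.15e-6
gold	19.3	42.6e-6	3240	128.8	3.47	6.3e7	128e-6
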