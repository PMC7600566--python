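# Reference adult male physiology v1 (81 kg): perfusion-tissue volumes as
# fraction of body weight (L/kg, density ~1) and blood flows as fraction of
# cardiac output. The liver flow entry is the hepatic artery only; portal
# inflow is the sum of gut, spleen and pancreas flows, so total hepatic flow
# fraction is 0.065+0.15+0.03+0.01 = 0.255 of cardiac output. Muscle carries
# the rest-of-body remainder so systemic flow fractions sum to 1.
tissue,volume_frac_bw,flow_frac_co
adipose,0.190,0.050
bone,0.086,0.050
brain,0.020,0.120
gut,0.0171,0.150
heart,0.0047,0.040
kidney,0.0044,0.190
liver,0.0204,0.065
lung,0.0076,0.0
muscle,0.400,0.245
pancreas,0.0017,0.010
skin,0.0371,0.050
spleen,0.0026,0.030
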