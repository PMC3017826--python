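# classic (PtdIns(3)P) binding signature
wxxd	W-x(2)-D
central_classic	R-[RK]-H-H-C-R
central_classic_core	[RK]-H-H-C-R
rvc	R-[VI]-C
# plant variant signature
wxxg	W-x(2)-G
central_variant	[KR]-[RK]-H-N-C-Y
lyr	[LFP]-Y-R
class_v_accessory	[HKN]-x(2)-[ST]-[SN]-[KR]-K
# class V conserved dimer-interface residues
axxap	A-x(2)-A-P
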