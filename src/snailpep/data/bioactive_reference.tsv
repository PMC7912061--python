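sequence	activity_class	source
YG	ACE-inhibitory	Drevet
YA	ACE-inhibitory	Drevet
VY	ACE-inhibitory	Drevet
FG	ACE-inhibitory	Drevet
GF	ACE-inhibitory	Drevet
DF	ACE-inhibitory	Drevet
SF	ACE-inhibitory	Drevet
VW	ACE-inhibitory	Drevet
HTYHEVTKH	antioxidant	Babylonia areolata hydrolysate
WPVLAYHFT	antioxidant	Babylonia areolata hydrolysate
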