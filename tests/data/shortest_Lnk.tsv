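Atg1	negative_feedback	Atg1(active) -> S6k(inactive) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp2	negative_feedback	Ilp2(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp3	negative_feedback	Ilp3(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp5	negative_feedback	Ilp5(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp6	negative_feedback	Ilp6(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
ImpL2	negative_feedback	ImpL2(inactive) -> Ilp2(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
ImpL2	negative_feedback	ImpL2(inactive) -> Ilp5(active) -> InR(active) -> chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Lnk	primary	Lnk(inactive) -> Pi3K(inactive) -> Akt1(inactive) -> foxo(active) -> longevity(active)
chico	negative_feedback	chico(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
wdb	negative_feedback	wdb(inactive) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
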