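Ilp2	negative_feedback	Ilp2(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp3	negative_feedback	Ilp3(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Ilp5	negative_feedback	Ilp5(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
chico	primary	chico(inactive) -> Pi3K(inactive) -> Akt1(inactive) -> foxo(active) -> longevity(active)
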