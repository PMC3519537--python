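InR	primary	InR(inactive) -> Lnk(inactive) -> Pi3K(inactive) -> Akt1(inactive) -> foxo(active) -> longevity(active)
InR	primary	InR(inactive) -> chico(inactive) -> Pi3K(inactive) -> Akt1(inactive) -> foxo(active) -> longevity(active)
L	negative_feedback	L(active) -> c_TOR-C1(inactive) -> c_TOR-C2(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Tak1	positive_feedback	Tak1(active) -> hep(active) -> bsk(active) -> foxo(active) -> longevity(active)
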