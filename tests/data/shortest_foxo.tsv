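Pk61C	positive_feedback	Pk61C(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
Pten	positive_feedback	Pten(inactive) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
foxo	primary	foxo(inactive) -> longevity(inactive)
hpo	positive_feedback	hpo(inactive) -> foxo(inactive) -> longevity(inactive)
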