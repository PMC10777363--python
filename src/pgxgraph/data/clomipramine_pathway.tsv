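From	To	Reaction Type	Controller
Clomipramine	Desmethylclomipramine	biochemical	CYP3A4, CYP2C19, CYP1A2
Clomipramine	2-Hydroxyclomipramine	biochemical	CYP2D6
Desmethylclomipramine	2-Hydroxydesmethylclomipramine	biochemical	CYP2D6
Clomipramine	Clomipramine N-oxide	biochemical	CYP3A4
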