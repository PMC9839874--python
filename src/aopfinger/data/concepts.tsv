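pattern	replacement	kind
positive regulation	upregulated	phrase
negative regulation	downregulated	phrase
increased	increase	root
increasing	increase	root
increases	increase	root
decreased	decrease	root
decreasing	decrease	root
decreases	decrease	root
activated	activation	root
activating	activation	root
inhibited	inhibition	root
inhibiting	inhibition	root
pparα	ppar-alpha	root
pparalpha	ppar-alpha	root
ppar-alpha	ppar-alpha	root
upregulated	upregulated	root
downregulated	downregulated	root
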