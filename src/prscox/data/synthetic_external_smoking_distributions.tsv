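level	proportion	source	reference
never	0.55	external:hse_like	never
former	0.27	external:hse_like	never
current	0.18	external:hse_like	never
never	0.45	external:epic_like	never
former	0.317	external:epic_like	never
current	0.233	external:epic_like	never
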