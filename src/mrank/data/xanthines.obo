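format-version: 1.2
ontology: xanthines
remark: synthetic mini-ontology of the xanthine family for tests and demos

[Term]
id: CHEBI:27732
name: caffeine
synonym: "1,3,7-trimethylxanthine" EXACT []
is_a: CHEBI:25348 ! methylxanthine

[Term]
id: CHEBI:28946
name: theobromine
synonym: "3,7-dimethylxanthine" EXACT []
is_a: CHEBI:25348 ! methylxanthine

[Term]
id: CHEBI:25348
name: methylxanthine
is_a: CHEBI:17712 ! xanthine

[Term]
id: CHEBI:17712
name: xanthine
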