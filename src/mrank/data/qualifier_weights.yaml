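# Default importance per BioModels.net qualifier name.
# bqbiol and bqmodel vocabularies share one weight per qualifier name.
is: 2.0
isHomologTo: 1.7
hasPart: 1.5
isPartOf: 1.5
isVersionOf: 1.5
hasVersion: 1.5
isEncodedBy: 1.3
isDerivedFrom: 1.3
encodes: 1.3
isDescribedBy: 1.0
occursIn: 1.0
hasProperty: 1.0
isPropertyOf: 1.0
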