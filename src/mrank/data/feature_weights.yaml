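# Default per-feature weights, grouped by dimension.
# Constituents (description)
modelName: 4
species: 3
compartment: 3
reaction: 3
parameter: 1.5
event: 1.5
function: 1.5
modelDescription: 0.5
# Constituents (URI)
modelURI: 5
speciesURI: 5
compartmentURI: 5
reactionURI: 5
parameterURI: 3
eventURI: 3
functionURI: 3
# Persons
author: 4
encoder: 1
submitter: 1
# Publication
publicationURI: 5
publicationText: 2.5
# User generated content
content: 1
# Dates
creationDate: 1
modificationDate: 1
# Administrative data
id: 1
additionalID: 1
path: 1
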