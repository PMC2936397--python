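{
  "urn:miriam:obo.chebi:CHEBI%3A27732": "caffeine chebi 27732 chebi home advanced search browse ontology periodic molecules chebi main caffeine chebi 116485 central nervous system stimulant caffeine ryanodine receptor modulator mutagen 1,3,7-trimethyl-3,7-dihydro-1h-purine-2,6-dione iuphar 1,3,7-trimethylxanthine dion msdchem d00528 kegg drug",
  "urn:miriam:kegg.compound:C07481": "kegg compound c07481 entry c07481 compound name caffeine 1,3,7-trimethylxanthine formula c8h10n4o2 mass 194.0804 structure remark d00528 comment source coffea arabica tax 13443 xanthines reaction r07920 r07921 27732 knapsack c00001492",
  "urn:miriam:kegg.compound:C00385": "kegg compound c00385 name xanthine formula c5h4n4o2 mass 152.0334 ko00230 purine metabolism caffeine metabolism",
  "urn:miriam:kegg.compound:C00048": "kegg compound c00048 entry c00048 glyoxylate glyoxylic acid formula c2h2o3 mass 74.0004 structure reaction r00013 r00364 purine metabolism path ko00232 caffeine metabolism glycine serine threonine metabolism"
}
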