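{
 "bioassay_catalog.json": "6356c72aca4ad6236fef53f93e9b650e6a75af58553bbe9e5215a46a7673e50d",
 "compounds.json": "d993d4b504998ba119db197d75f722a9637e61cceca7c19c2166fe75ed341056"
}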