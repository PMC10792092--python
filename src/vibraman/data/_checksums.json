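{
  "table1_clopidogrel_arginine.tsv": "27c2047d2413f138b9aaac8cf6ed8ca3cbe9692428f2ed329f1aa1ad8197b6e6",
  "table2_aspirin_arginine.tsv": "d11d194e0c66b8ba45e9a3a112c23a055c853e490df091cd8781071113c5252f",
  "table3_biomarkers.tsv": "57303ba6f0623f755493f143ce33df5348881c2cfa6034acdbd393125efcd48e",
  "aspirin_table3_override.json": "02f9a9fb6b58a7c4c449767bb234d850dc3ba05869fccc108197dbf6438e5657"
}
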