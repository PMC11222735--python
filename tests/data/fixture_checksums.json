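{
 "availability.csv": "beba35d6c3b240b89b70489fd9cf4442ec23d149f4094500be1878f9287ff9a4",
 "diet_profiles.csv": "a0633676270cb7bdd7f85bc5540199b2133c40bfc85d6f7add2aa031657b0dec",
 "diet_scores.csv": "51267ee9aa3a40eeb028727efc93dcf5b4a39be836f7f793e0ee38b6f3a4666a",
 "dissimilarity.csv": "b15e9ac34bce956f1baace02306e87d03c9083a745d0b899a0ccda83daa89437",
 "exclusions.csv": "b7add02ad94599be8c752a9840569fc8c448e56970005325d87d417344cbc131",
 "genotypes_replicates.csv": "83655efc7f25f8aebe96ce7b1d5a4cf92cca2956732a11a4313a1bcb3444b90e",
 "individuals.csv": "fe1f127ac11e14f2f7974d3299a8ea471d2e1fa41ebb2a82235fdc5e98954358",
 "match_audit.csv": "38cceac1dcb1e3f6fec65e4779d1c1edbca7dca219e5badfa32631f0736f53cf",
 "period_means.csv": "417ae13f059ac78f015711876bd1ff7ecb9a950b97c6bd74bf18565caabceee5",
 "period_tests.csv": "6752cfa2dee6be5807d85d457e7aeb1d1e050b706ff53175b58759f99c162ccd",
 "periods.csv": "a9cde6a2295de8588e147e677459ce25c76685becdf2e8fcfeaadf695579946e",
 "pulse_segments.csv": "bc290bf1a5933dec23b7e7d8f66f2979e034fa9752ff35d1cf3b93131f6e9d43",
 "pulse_share.csv": "800c96dffc05b4c57f0c3ef987cb449d9f93927a61d4dea8c33d72ffb6bb9010",
 "reference_panel.csv": "3c32224861e076eed2d5ff9d9524e2684778d46bb14f5c63532d7b7ca60ad107",
 "retained_scats.csv": "159fd6788cedeb36343308d90c060e284c79acfe86aab17c1c5141544bccbe4b",
 "scats.csv": "cc6e23bc398f8a2eb31bc73722f6ddc6b9f982d32254b8c05b595f148de2d3d2",
 "segment_consumption.csv": "951f9c0021e16f7bb8dba7851df0dc17eafc30f1785aeb6540475f161e570a49",
 "segment_models.csv": "43e0bb86930b23ac558299dfa72e00d1898b0c521e4b581ab751462825908765",
 "sex_models.csv": "7c5d73d15e89dbc4460a5698c2a47a25fc70dbcd9c2891dbf32fbba351d83625",
 "species_calls.csv": "7e4351f6dcb467b9945ecfb8399da5772e8c818c7651b54a61262b7b32ba9648",
 "truth.json": "13041fa4d23e234ca730bbdd7e36488db4ac33d4f7351eed8e6da18f03803a67"
}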