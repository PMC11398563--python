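{
  "outputs": {
    "counts.tsv": "cb99617fb629034c9226a5a16c9b5db80d72cd996d2cac28b45b8c903838701e",
    "diff.tsv": "a18ab82d1cda4eca0179326cf0d4c9d779f4cf94a80a270d26f87bd2b4b1a4ab",
    "ecdna_binmap.tsv": "31356c234c5762b92a941d2e25558c84fa67b368593a9b0fe68c7dc0302c4de8",
    "ecdna_matrix.tsv": "05d079bf18dd5e93df137b647f88ae5024ad863664e5d6f604d087f8d43f7b23",
    "hic_compare.tsv": "0f9e2d73f1fb5258765b691bc482d5eee22bde6a7312518dbaac14aae4989657",
    "k27ac_in_k4me1.bed": "fa336cef9086358ed0a2aa67f2716ac248babb5755407c5dfffb08034f719087",
    "samples.tsv": "209dc0d149511c1ed2b28acdcd120adcb3c4b67ccde910c3ea2c5f8bc9611980"
  }
}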