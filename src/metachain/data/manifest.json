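{
  "lung_edges.tsv": "192d47254d17d7d0b5e7f6ae3bf53ed5e671d7cf9bb52eb4a98777eae7fead9a",
  "mfpt_lung.tsv": "801a7f02e9b0ab5e907fa02d211cf3084400f4b0e6802f3086477e1ada447917",
  "self_edges.tsv": "60b63693f54edda176d0782e3fe96b8432c6b3915e8da7d59c9a430cb931c5c8",
  "sites.tsv": "dfa37bc749cf3d8a6420bb0914187761e3b6e558e0cacc7cde0468d23d6fcd1f",
  "dataset.json": "e3ca02386ccad44476d7a3957bd7ee5ac3b91947b89371932a55ef5581291ffc"
}
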