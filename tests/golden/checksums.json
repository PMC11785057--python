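{
  "sequences.fasta": "4c5a29ab679472a48e513e22d149b9e3639f740c4279e09f2a46838f45874437",
  "labels.tsv": "863bc9dfe1e7db2d6d34d3aab33215821a78a57c166a102b293aab0c7421b4c3",
  "truth.yaml": "38ccd422dbc0cc73e8dbdcb45586496806c296a866d970273ba9b968ea264176",
  "profiles.tsv": "862423a35759366fe6bbd89b5a6d68441e6c9f64bfe5f1f7f626b830e12a3ce1",
  "matches.tsv": "5d53589534086262b104a7fab8765352aae819517d8efcea21a58e8ec801a139",
  "matches.bed": "eacd4082c85098a5889206027a1b5066af490569d8d675bd5ecd2e97751dc5e9",
  "features.tsv": "90315e3aab59ea4024d5c2a4e8223de9e889ac7c302340631aaad6f6a808143b",
  "results.tsv": "057ad8a21eba6d03c9bd882a1916c6f9f3fbdee43a558d25a9c0016b290200eb"
}
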