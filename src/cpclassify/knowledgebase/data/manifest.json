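{
  "T1.tsv": "852cd748ce1d893f5227009538a079e22dc93c227620b48a42d230b5bcaf36cb",
  "T2.tsv": "3551837c0ddbe33338f3d093d58e64de4c908ce106b6463c84115795279a5f32",
  "T3.tsv": "d049f4d4817c203596f9cf9ba6500cb7a8b24595e640d5ad55e38b01e2b46efe",
  "T4.tsv": "f87dea2fc1c4c02c83f0bc76d13cfc525c4b2a485218364fb28160f3b9f3bf7c",
  "T5.tsv": "97f1ee3ead6a8c7c723bb09fed3589ffcc153ea6bdb310aaae9f59d38dd76875",
  "T6.tsv": "8883052f9d0a8925b4e0f91b750a9b3d10f0a23276c839a33d1d6008125de243",
  "genes.json": "9cbc1ed2c0bac61681f5a209e772051e189ea6e80acf351f18cf13cf353f5eeb",
  "provenance.json": "45bb810a4e218cac9879113dd787de872ef8fe897a69eca5178b8317f73e18d8",
  "reclassification.tsv": "55728d9cb9f5db339ec9b0801fb78d518307ec59e5f28bf443488d61cc1ff2e8"
}
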