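{
 "table1_presence.tsv": "1f415de227cb3a4447c0fb6aa10d18afc356836a316bf6bb60b525fde8894afe",
 "table3_precursors.tsv": "1e6738c600f7cdcc3952591868f78a9a2e6bb9e346b96e421369ac398827ff9b",
 "synthetic_anchor_panel.faa": "3f6c6c8947d1c86bc9848b30ca5278a8715815d428619e3742356fb3400a79f7",
 "synthetic_core_panel.faa": "83b64a0af6c3981ba1e735dd4efad9410dfd251fddc1656713cc5fa0c93b8b9e"
}
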