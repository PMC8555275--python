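{
  "igap": {
    "file": "outcome_igap.tsv",
    "label": "IGAP AD",
    "binary": true,
    "n_total": 63926,
    "n_cases": 21982
  },
  "ukb_proxy": {
    "file": "outcome_ukb_proxy.tsv",
    "label": "UK Biobank AD proxy",
    "binary": true,
    "n_total": 314278,
    "n_cases": 42034
  },
  "ukb_maternal": {
    "file": "outcome_ukb_maternal.tsv",
    "label": "Maternal AD group from UK Biobank",
    "binary": true,
    "n_total": 288676,
    "n_cases": 27696
  },
  "ukb_paternal": {
    "file": "outcome_ukb_paternal.tsv",
    "label": "Paternal AD group from UK Biobank",
    "binary": true,
    "n_total": 260279,
    "n_cases": 14338
  },
  "cognitive": {
    "file": "outcome_cognitive.tsv",
    "label": "Cognitive performance",
    "binary": false,
    "n_total": 257841,
    "n_cases": null
  }
}
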