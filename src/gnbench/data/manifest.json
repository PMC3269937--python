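{
 "table3": {
  "sha256": "172cc7be5e0bb186df6101ded4f35f73d03ea475d5df9a81c4e186e535b9d97d",
  "rows": 36,
  "cols": 4
 },
 "table4": {
  "sha256": "29cdee5f461ebbc9a78a79a910d1243793790fac53ebddda7a39237be069e74e",
  "rows": 36,
  "cols": 7
 },
 "table5": {
  "sha256": "c14d6733aca43421b6de0d649322ea8bce48f8d32eefd36c33ac1119b39bc1de",
  "rows": 4,
  "cols": 4
 }
}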