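{
  "_comment": "Synthetic example signature panels for demonstration and testing. These are small illustrative gene sets, NOT the proprietary commercial classifier gene lists; edit or replace with real panels as plain JSON. 'up' = over-expressed in aggressive disease (red marker), 'down' = under-expressed (blue marker).",
  "CCP": {"up": ["MKI67", "CCNB1", "TOP2A"], "down": []},
  "Decipher": {"up": ["TRPM8"], "down": ["KLK3", "MYBPC1"]},
  "GPS": {"up": ["GCNT1"], "down": ["KLK2", "CHRNA2"]}
}
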