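{
  "description": "Published 2x2 counts of preoperative blood-test use by institution bed-size class, from a nationwide Japanese claims cohort of 69,252 low-risk surgeries at 9,922 institutions (study window 2012-04-01 to 2016-03-31).",
  "z_small": 18993,
  "n_small": 41157,
  "z_large": 21829,
  "n_large": 28095
}
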