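{
  "comment": "Curated membership override for the aspirin/arginine biomarker list: two single-fragment modes are force-included and two joint modes are force-excluded relative to the default joint-mode rule.",
  "include": [37, 45],
  "exclude": [43, 110]
}
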