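{
 "adult.csv": "76688d5631af0627b13264ec9dff0fdefc754a5bc25dd7ebb9acc912f0c20366",
 "baby.csv": "f9857de8a1a920adaba1f4d68f73ff053fe8b7cdf7d05b41c201ed822961474a"
}
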