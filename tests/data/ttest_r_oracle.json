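{
  "welch_4v4": {
    "t": -9.85900603509299,
    "df": 5.999999999999998,
    "p": 6.280125725146638e-05
  },
  "student_8v9": {
    "t": -4.1557587582061934,
    "df": 15,
    "p": 0.0008452132670301948
  },
  "welch_8v9": {
    "t": -4.157336953807567,
    "df": 14.788031138205493,
    "p": 0.000866757090089931
  }
}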