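# Published summary counts for the quinolone-pemphigoid reporting cohort
# (183 deduplicated reports) and the reconstructed ciprofloxacin
# time-to-onset bin counts (29 reports with computable latency). These are
# worked-example *inputs*: the package recomputes every percentage from
# these counts.
table2:
  drug:
    CIPROFLOXACIN: 48
    LEVOFLOXACIN: 42
    MOXIFLOXACIN: 4
    NORFLOXACIN: 3
    OFLOXACIN: 86
  sex:
    F: 102
    M: 57
    NS: 24
  age:
    "<18": 2
    "18-44": 27
    "45-64": 34
    ">=65": 88
    "NS": 32
  weight:
    "<80": 35
    ">=80": 15
    "NS": 133
  occupation:
    CN: 7
    MD: 71
    NS: 11
    OT: 74
    PH: 20
  region:
    Asia: 1
    Europe: 9
    North America: 3
    Others: 170
  outcome:
    DE: 1
    HO: 123
    NS: 17
    OT: 42
ciprofloxacin_tto_bins:
  "0-30": 25
  "31-60": 3
  "61-90": 0
  "91-359": 0
  ">=360": 1
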