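# Study-drug dictionary: canonical names, trade-name synonyms, FDA approval
# dates (YYYYMMDD, defining each drug's reporting period) and inclusion flags.
# The three excluded quinolones carry include: false rather than being
# removed, so exclusion stays a configuration decision.
drugs:
  OFLOXACIN:
    synonyms: [Floxin, Tarivid, Ofloxacine]
    approval_date: 19901228
    include: true
  CIPROFLOXACIN:
    synonyms: [Cipro, Cipro XR, Ciproxin]
    approval_date: 19871022
    include: true
  LEVOFLOXACIN:
    synonyms: [Levaquin, Cravit]
    approval_date: 19961220
    include: true
  MOXIFLOXACIN:
    synonyms: [Avelox]
    approval_date: 19991210
    include: true
  NORFLOXACIN:
    synonyms: [Noroxin]
    approval_date: 19861031
    include: true
  GEMIFLOXACIN:
    synonyms: [Factive]
    approval_date: 20030404
    include: false
  GATIFLOXACIN:
    synonyms: [Tequin]
    approval_date: 19991217
    include: false
  LOMEFLOXACIN:
    synonyms: [Maxaquin]
    approval_date: 19920221
    include: false
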