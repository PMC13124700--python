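# Preferred terms defining the target event (case-insensitive exact match).
terms:
  - Pemphigoid
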