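"""Physical constants shared across modules."""

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987204e-3

#: heavy-atom contact cutoff, Angstrom (strict less-than)
CONTACT_CUTOFF = 4.5

#: unwrapped-bp displacement threshold, Angstrom
UNWRAP_THRESHOLD = 7.0

#: default analysis temperature, K
DEFAULT_TEMPERATURE = 310.0
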