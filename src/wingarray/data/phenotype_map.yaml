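# Wing-tissue color phenotypes, per (wing, morph, section).
#
# Forewing sections are dissected along color-pattern boundaries; the distal
# section is black in both morphs and acts as the within-morph control tissue.
# Hindwings are hybridized whole and each race is classified as a single
# color (rayed = red, yellow-barred = yellow, plain = black), even though the
# red and yellow hindwings also carry substantial black area.
forewing:
  petiverana:
    proximal: black
    medial: red
    distal: black
  hybrid:
    proximal: red
    medial: yellow
    distal: black
hindwing:
  emma:
    whole: red
  favorinus:
    whole: yellow
  amphitrite:
    whole: black
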