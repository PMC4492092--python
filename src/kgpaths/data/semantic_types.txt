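# Semantic types admitted during concept-annotation filtering.
Organisms
Clinical Drug
Substances
Sign or Symptom
Anatomical Structure
Molecular Sequence
Body Space or Junction
Body Location or Region
Pathologic Function
Injury or Poisening
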