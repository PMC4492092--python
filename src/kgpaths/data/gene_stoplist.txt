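# Common English words frequently mis-annotated as gene/protein concepts
# (gene aliases that collide with ordinary vocabulary). One word per line;
# matching is case-insensitive on the annotation's surface form.
impact
rare
an
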