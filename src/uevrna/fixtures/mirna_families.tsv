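family_label	members
miR-30s	miR-30a,miR-30b,miR-30c,miR-30d,miR-30e
miR-379 megacluster	miR-379
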