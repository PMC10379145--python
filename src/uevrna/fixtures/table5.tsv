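mirna_id	cluster	direction_study	direction_literature
miR-30b-5p	c1	down	down
miR-221-3p	c1	down	down
miR-15b-5p	c1	down	up
let-7f-1-3p	c1	down	down
let-7a-3p	c1	down	down
miR-424-5p	c4	up	up
miR-486-3p	c4	up	up
miR-335-5p	c4	up	up
miR-126-3p	c4	up	up
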