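mirna_id	direction	sample_type	reference
miR-619	up	urine	B148
miR-486-3p	up	urine	B148
miR-335-5p	up	urine	B148
miR-552	up	urine	B148
miR-1912	up	urine	B148
miR-1124-3p	up	urine	B148
miR-424-5p	up	urine	B148
miR-141-3p	up	urine	B148
miR-29b-1-5p	up	urine	B148
miR-221-3p	down	urine	B148
miR-214-3p	up	urine	B148
miR-92b-5p	up	urine	B148
miR-765	up	urine	B148
miR-429	up	urine	B148
miR-373-5p	up	urine	B148
miR-1913	up	urine	B148
miR-638	up	urine	B148
miR-323b-5p	down	urine	B148
miR-524-5p	down	urine	B148
miR-188-3p	down	urine	B148
miR323b-5p	up	urine	B148
miR-433	up	urine	B148
miR-17-5p	up	urine	B148
miR-222-3p	up	urine	B148
628-5p	up	urine	B148
miR-589-5p	down	urine	B148
miR92a-3p	down	urine	B148
miR-200c	up	urinary_sediments	B149
miR-638	down	urinary_sediments	B149
miR-192	down	urinary_sediments	B149
miR-130a	up	uEV	B112
miR-145	up	uEV	B112
miR-155	down	uEV	B112
miR-424	down	uEV	B112
miR-126	up	urine	B150
miR-192	up	uEV	B27
miR-194	up	uEV	B27
miR-215	up	uEV	B27
miR-192	down	uEV	B27
miR-215	down	uEV	B27
miR-320c	up	uEV	B151
miR-6068	up	uEV	B151
miR-15b	up	urine_pellets_uEV	B152
miR-34a	up	urine_pellets_uEV	B152
miR-636	up	urine_pellets_uEV	B152
miR-877-3p	up	uEV	B153
miR-26a-1-5p	up	uEV	B59
miR-30-5p	up	uEV	B59
miR-200c-3p	up	uEV	B59
miR144-3p	down	uEV	B59
miR10a-5p	up	urine	B59
miR-200a-3p	up	urine	B59
miR-126-3p	up	urine	B91
miR-155-5p	up	urine	B91
miR-29b-3p	up	urine	B91
miR-30e-5p	down	urine	B154
miR-21-5p	up	uEV	B28
miR-30b-5p	down	uEV	B28
miR-27-3p	down	urine	B155
miR-1228	down	urine	B155
miR-15b-5p	up	uEV	B72
miR-30e-3p	down	uEV	B156
miR-30c-5p	down	uEV	B156
miR-190a-5p	down	uEV	B156
miR-98-3p	down	uEV	B156
let-7a-3p	down	uEV	B156
miR-30b-5p	down	uEV	B156
let-7f-1-3p	down	uEV	B156
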