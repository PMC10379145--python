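mirna_id	direction	reference
let-7b-5p	down	B71
miR-15b-5p	up	B72
miR-16-5p	down	B73
miR-20b-5p	up	B74
miR-21-5p	down	B48
miR-21-5p	up	B46
miR-21-5p	up	B47
miR-21-5p	unknown	B75
miR-21-5p	up	B76
miR-21-5p	up	B77
miR-21-5p	up	B78
miR-21	up	B79
miR-22	up	B80
miR-23a-3p	up	B81
miR-23b-3p	down	B82
miR-23b	down	B83
miR-25-3p	down	B84
miR-25-3p	down	B85
miR-25-3p	down	B86
miR-25	down	B87
miR-26a-5p	down	B88
miR-27a-3p	up	B89
miR-27a	up	B90
miR-29b-3p	up	B91
miR-29b-3p	down	B92
miR-29c-3p	up	B93
miR-29a	down	B94
miR-29a	down	B95
miR-29a/b/c family	down	B96
miR-30e-5p	down	B97
miR-30s (family)	down	B98
miR-30b-5p	down	B99
miR-30c-5p	down	B100
miR-34a-5p	up	B101
miR-34a-5p	up	B102
miR-34c-5p	down	B103
miR-93-5p	down	B104
miR-124-5p	up	B105
hsa-miR-126-3p	up	B91
miR-130a-3p	down	B106
miR-130b-5p	down	B107
miR-133b	up	B108
miR-134-5p	up	B109
miR-135a-5p	up	B110
miR-140-5p	down	B111
miR-145-5p	up	B112
miR-145-5p	down	B113
miR-146a-5p	up	B114
miR-146a-5p	down	B115
miR-146a	down	B116
miR-146a	down	B117
miR-155-5p	up	B114
miR-155-5p	up	B91
miR-155-5p	up	B118
miR-181a-5p	down	B119
miR-192-5p	up	B120
miR-192-5p	down	B51
miR-192-5p	up	B121
miR-192	mixed	B27
miR-192	down	B50
miR-192	up	B122
miR-193a	up	B123
miR-195	down	B124
miR-196a-5p	down	B125
miR-199a-3p	down	B126
miR-199b-5p	up	B108
miR-200a-3p	down	B127
miR-200 b/c-3p	up	B121
miR-200 b/c	up	B128
miR-214-3p	up	B129
miR-214-3p	up	B130
miR-215-5p	down	B51
miR-216a-5p	up	B131
miR-216a-5p	up	B132
miR-217-5p	up	B133
miR-217-5p	up	B131
miR-218-5p	up	B134
miR-301a-3p	down	B106
miR-342-3p	down	B135
miR-374a	down	B136
miR-377-3p	up	B137
miR-379-5p	down	B138
miR-379 megacluster	up	B139
miR-423-5p	down	B140
miR-451a	down	B141
miR-451a	mixed	B142
miR-503	up	B143
miR-770-5p	up	B144
miR-874	up	B145
miR-874	down	B146
miR-1207-5p	up	B147
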