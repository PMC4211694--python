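category	mirna_type
brain_shared	let-7
brain_shared	let-7a-1-3p
brain_shared	let-7i-3p
brain_shared	miR-99-3p
brain_shared	miR-18a
brain_shared	miR-106
brain_shared	miR-10d
brain_shared	miR-124
brain_shared	miR-124a
brain_shared	miR-125b-1-3p
brain_shared	miR-129-1-3p
brain_shared	miR-129-3p
brain_shared	miR-129-5p
brain_shared	miR-130b
brain_shared	miR-132
brain_shared	miR-132-5p
brain_shared	miR-212
brain_shared	miR-135
brain_shared	miR-135b
brain_shared	miR-137
brain_shared	miR-137-5p
brain_shared	miR-137b
brain_shared	miR-138
brain_shared	miR-138-1-3p
brain_shared	miR-138-2-3p
brain_shared	miR-138b
brain_shared	miR-142-5p
brain_shared	miR-150
brain_shared	miR-153-5p
brain_shared	miR-153b
brain_shared	miR-22-5p
brain_shared	miR-22b
brain_shared	miR-23b-3p
brain_shared	miR-24-1-5p
brain_shared	miR-92a
brain_shared	miR-27b
brain_shared	miR-27b-5p
brain_shared	miR-365
brain_shared	miR-34a
brain_shared	miR-7-1-3p
brain_shared	miR-9a
brain_shared	miR-9a-3p
brain_shared	miR-9-3p
brain_shared	miR-181a-3p
brain_shared	miR-182
brain_shared	miR-183
brain_shared	miR-187
brain_shared	miR-190a-3p
brain_shared	miR-200b
brain_shared	miR-203b-5p
brain_shared	miR-216
brain_shared	miR-218
brain_shared	miR-218b
brain_shared	miR-219
brain_shared	miR-219-2-3p
brain_shared	miR-221-5p
brain_shared	miR-222a-5p
brain_shared	miR-301a
brain_shared	miR-301c
brain_shared	miR-375
brain_shared	miR-454
brain_shared	miR-455
brain_shared	miR-456
brain_shared	miR-458
brain_shared	miR-460b-3p
brain_shared	miR-489
brain_shared	miR-723
brain_shared	miR-724
brain_shared	miR-727
brain_shared	miR-727-5p
brain_shared	miR-728
brain_shared	miR-734
brain_shared	miR-737
brain_shared	miR-338
brain_shared	miR-2187
brain_shared	miR-2188-3p
brain_shared	miR-2188
brain_female_only	miR-20b
brain_female_only	miR-124-5p
brain_female_only	miR-133
brain_female_only	miR-83
brain_female_only	miR-184
brain_female_only	miR-203a
brain_female_only	miR-205a
brain_female_only	miR-725
brain_female_only	miR-962-3p
brain_male_only	let-7a-2-3p
brain_male_only	miR-17-3p
brain_male_only	miR-124-3p
liver_shared	miR-122
liver_shared	miR-122-3p
liver_shared	miR-148
liver_shared	miR-192
liver_shared	miR-199
liver_female_only	miR-4448
liver_male_only	miR-199b-3p
liver_male_only	miR-749
gonad_shared	miR-196
gonad_shared	miR-196a
gonad_shared	miR-202
gonad_shared	miR-202-5p
ovary_only	miR-27a
ovary_only	miR-1692
testis_only	miR-2895
testis_only	miR-4682
testis_only	miR-2184
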