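label	group	n_without	n_with	denom_without	denom_with
total	overall	2641405	24073
male	sex	1360311	3412
female	sex	1281094	20661
1973-1977	birth_year	462044	3299
1978-1982	birth_year	420446	4063
1983-1987	birth_year	437434	5210
1988-1992	birth_year	538404	6125
1993-1997	birth_year	463787	3963
1998-2001	birth_year	319290	1413
alcohol_use_disorder	phenotype	109169	7780
drug_use_disorder	phenotype	77165	9110
schizophrenia_spectrum_disorder	phenotype	23149	2782
bipolar_disorder	phenotype	32398	6391
depressive_disorder	phenotype	218851	18432
anxiety_disorder	phenotype	99742	9331
ocd	phenotype	29663	2764
acute_stress_reaction	phenotype	57053	6850
ptsd	phenotype	21602	4920
adjustment_disorder	phenotype	69895	6386
anorexia_nervosa	phenotype	14091	1618
other_eating_disorder	phenotype	28827	4384
other_specific_personality_disorder	phenotype	7738	2558
intellectual_disability	phenotype	175695	10427
autism_spectrum_disorder	phenotype	53255	2788
adhd	phenotype	128488	9144
conduct_disorder	phenotype	12240	1261
childhood_anxiety	phenotype	2855	301
tic_disorder	phenotype	8156	216
epilepsy	phenotype	39067	1058
cerebral_palsy	phenotype	6844	58
migraine	phenotype	79515	1815
sleep_disorder	phenotype	82079	4926
type_1_diabetes	phenotype	26559	438
type_2_diabetes	phenotype	13286	458
autoimmune_disease	phenotype	160937	2379
congenital_hypothyroidism	phenotype	1614	35
cystic_fibrosis	phenotype	576	5
anaphylaxis	phenotype	17995	367
asthma	phenotype	208236	3356
infections	phenotype	1009137	15801
cardiovascular_disease	phenotype	113957	2108
pcos	phenotype	29159	904	1281094	20661
sexual_pain	phenotype	133421	4761	1281094	20661
gastrointestinal_problems	phenotype	73690	1949
fatigue_aches	phenotype	10223	737
joint_pain	phenotype	369684	4925
accidental_fall	phenotype	898744	10716
accidental_poisoning	phenotype	49703	2399
transport_accident	phenotype	379131	5310
traumatic_brain_injury	phenotype	261022	4347
assault_victimization	phenotype	98054	4113
self_harm	phenotype	102349	11763
suicide	phenotype	6297	636
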