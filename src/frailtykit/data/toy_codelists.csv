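deficit_name,code
arthritis,D00A
arthritis,D00B
arthritis,D00C
arthritis,D00D
atrial fibrillation,D01A
atrial fibrillation,D01B
atrial fibrillation,D01C
atrial fibrillation,D01D
cerebrovascular disease,D02A
cerebrovascular disease,D02B
cerebrovascular disease,D02C
cerebrovascular disease,D02D
diabetes,D03A
diabetes,D03B
diabetes,D03C
diabetes,D03D
falls,D04A
falls,D04B
falls,D04C
falls,D04D
fragility fracture,D05A
fragility fracture,D05B
fragility fracture,D05C
fragility fracture,D05D
hearing impairment,D06A
hearing impairment,D06B
hearing impairment,D06C
hearing impairment,D06D
heart failure,D07A
heart failure,D07B
heart failure,D07C
heart failure,D07D
hypertension,D08A
hypertension,D08B
hypertension,D08C
hypertension,D08D
osteoporosis,D09A
osteoporosis,D09B
osteoporosis,D09C
osteoporosis,D09D
parkinsonism and tremor,D10A
parkinsonism and tremor,D10B
parkinsonism and tremor,D10C
parkinsonism and tremor,D10D
sleep disturbance,D11A
sleep disturbance,D11B
sleep disturbance,D11C
sleep disturbance,D11D
social vulnerability,D12A
social vulnerability,D12B
social vulnerability,D12C
social vulnerability,D12D
visual impairment,D13A
visual impairment,D13B
visual impairment,D13C
visual impairment,D13D
anaemia and haematinic deficiency,D14A
anaemia and haematinic deficiency,D14B
anaemia and haematinic deficiency,D14C
anaemia and haematinic deficiency,D14D
chronic kidney disease,D15A
chronic kidney disease,D15B
chronic kidney disease,D15C
chronic kidney disease,D15D
dyspnoea,D16A
dyspnoea,D16B
dyspnoea,D16C
dyspnoea,D16D
foot problems,D17A
foot problems,D17B
foot problems,D17C
foot problems,D17D
heart valve disease,D18A
heart valve disease,D18B
heart valve disease,D18C
heart valve disease,D18D
housebound,D19A
housebound,D19B
housebound,D19C
housebound,D19D
hypotension or syncope,D20A
hypotension or syncope,D20B
hypotension or syncope,D20C
hypotension or syncope,D20D
ischaemic heart disease,D21A
ischaemic heart disease,D21B
ischaemic heart disease,D21C
ischaemic heart disease,D21D
peptic ulcer,D22A
peptic ulcer,D22B
peptic ulcer,D22C
peptic ulcer,D22D
peripheral vascular disease,D23A
peripheral vascular disease,D23B
peripheral vascular disease,D23C
peripheral vascular disease,D23D
skin ulcer,D25A
skin ulcer,D25B
skin ulcer,D25C
skin ulcer,D25D
thyroid disease,D26A
thyroid disease,D26B
thyroid disease,D26C
thyroid disease,D26D
urinary incontinence,D27A
urinary incontinence,D27B
urinary incontinence,D27C
urinary incontinence,D27D
urinary system disease,D28A
urinary system disease,D28B
urinary system disease,D28C
urinary system disease,D28D
weight loss and anorexia,D29A
weight loss and anorexia,D29B
weight loss and anorexia,D29C
weight loss and anorexia,D29D
activity limitation,D30A
activity limitation,D30B
activity limitation,D30C
activity limitation,D30D
dizziness,D31A
dizziness,D31B
dizziness,D31C
dizziness,D31D
memory and cognitive problems,D32A
memory and cognitive problems,D32B
memory and cognitive problems,D32C
memory and cognitive problems,D32D
mobility and transfer problems,D33A
mobility and transfer problems,D33B
mobility and transfer problems,D33C
mobility and transfer problems,D33D
requirement for care,D34A
requirement for care,D34B
requirement for care,D34C
requirement for care,D34D
respiratory disease,D35A
respiratory disease,D35B
respiratory disease,D35C
respiratory disease,D35D
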