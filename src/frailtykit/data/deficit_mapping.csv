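ehr_deficit,survey_deficit,relation,note
arthritis,arthritis,one_to_one,
atrial fibrillation,atrial fibrillation,one_to_one,
cerebrovascular disease,stroke,one_to_one,
diabetes,diabetes or high blood sugar,one_to_one,
falls,falls,one_to_one,
fragility fracture,hip fracture,one_to_one,
hearing impairment,poor hearing,one_to_one,
heart failure,heart failure,one_to_one,
hypertension,high blood pressure,one_to_one,
osteoporosis,osteoporosis,one_to_one,
parkinsonism and tremor,parkinsons disease,one_to_one,
sleep disturbance,restless sleep,one_to_one,
social vulnerability,low social participation,one_to_one,
visual impairment,poor eyesight,one_to_one,
mobility and transfer problems,difficulty walking 100m,one_to_many,
mobility and transfer problems,difficulty climbing one flight of stairs without resting,one_to_many,
mobility and transfer problems,difficulty climbing several flights of stairs,one_to_many,
mobility and transfer problems,difficulty getting up from a chair,one_to_many,
mobility and transfer problems,difficulty stooping kneeling or crouching,one_to_many,
mobility and transfer problems,difficulty reaching or extending arms,one_to_many,
mobility and transfer problems,difficulty pulling or pushing large objects,one_to_many,
mobility and transfer problems,difficulty lifting or carrying 10 lbs,one_to_many,
mobility and transfer problems,difficulty picking up a 5p coin,one_to_many,
requirement for care,difficulty dressing,one_to_many,
requirement for care,difficulty walking across a room,one_to_many,
requirement for care,difficulty bathing or showering,one_to_many,
requirement for care,difficulty eating,one_to_many,
requirement for care,difficulty getting in and out of bed,one_to_many,
requirement for care,difficulty using the toilet,one_to_many,
requirement for care,difficulty using a map,one_to_many,
requirement for care,difficulty preparing a hot meal,one_to_many,
requirement for care,difficulty making telephone calls,one_to_many,
requirement for care,difficulty managing money,one_to_many,
memory and cognitive problems,poor self-rated memory,one_to_many,
memory and cognitive problems,difficulty with word recall,one_to_many,
memory and cognitive problems,difficulty with orientation to date,one_to_many,
respiratory disease,lung disease,one_to_many,
respiratory disease,asthma,one_to_many,
activity limitation,limited in activities due to health,one_to_many,
activity limitation,difficulty with heavy housework,one_to_many,
activity limitation,difficulty shopping for groceries,one_to_many,
activity limitation,difficulty with work around house or garden,one_to_many,
dizziness,dizziness on standing,one_to_many,
dizziness,balance problems,one_to_many,
dizziness,unsteadiness walking,one_to_many,
anaemia and haematinic deficiency,,one_to_none,
chronic kidney disease,,one_to_none,
dyspnoea,,one_to_none,
foot problems,,one_to_none,
heart valve disease,,one_to_none,
housebound,,one_to_none,
hypotension or syncope,,one_to_none,
ischaemic heart disease,,one_to_none,
peptic ulcer,,one_to_none,
peripheral vascular disease,,one_to_none,
polypharmacy,,one_to_none,
skin ulcer,,one_to_none,
thyroid disease,,one_to_none,
urinary incontinence,,one_to_none,
urinary system disease,,one_to_none,
weight loss and anorexia,,one_to_none,
,sadness,one_to_none,
,loneliness,one_to_none,
,feeling depressed,one_to_none,
,everything an effort,one_to_none,
,could not get going,one_to_none,
,lack of enjoyment,one_to_none,
,unhappiness,one_to_none,
,anxiety,one_to_none,
,poor self-rated health,one_to_none,
,poor appetite,one_to_none,
,trouble concentrating,one_to_none,
,feeling isolated,one_to_none,
,pessimism about future,one_to_none,
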