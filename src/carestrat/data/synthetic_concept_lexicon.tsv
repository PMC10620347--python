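concept	label	triggers	umls_mapped	source_vocabulary
Adjustment of quiet in the environment	ENV	quiet,room	true	SNOMED_US
Adjustment of space in the environment	ENV	space,schedule	true	CHV
Adjustment of routine in the environment	ENV	routine	true	NOC
Adjustment of timer in the environment	ENV	timer	true	PSY
Adjustment of music in the environment	ENV	music	true	NIC
Adjustment of headphone in the environment	ENV	headphone	true	RCD
Adjustment of picture in the environment	ENV	picture	true	SNOMED_US
Adjustment of chart in the environment	ENV	chart	true	CHV
Adjustment of calendar in the environment	ENV	calendar	true	NOC
Adjustment of light in the environment	ENV	light	true	PSY
Adjustment of noise in the environment	ENV	noise	true	NIC
Adjustment of corner in the environment	ENV	corner	true	RCD
Adjustment of desk in the environment	ENV	desk	true	SNOMED_US
Adjustment of seat in the environment	ENV	seat	true	CHV
Adjustment of ramp in the environment	ENV	ramp	true	NOC
Adjustment of rail in the environment	ENV	rail	true	PSY
Adjustment of door in the environment	ENV	door	true	NIC
Adjustment of furniture in the environment	ENV	furniture	true	RCD
Adjustment of visual in the environment	ENV	visual	true	SNOMED_US
Adjustment of cue in the environment	ENV	cue	true	CHV
Adjustment of reminder in the environment	ENV	reminder	true	NOC
Adjustment of checklist in the environment	ENV	checklist	true	PSY
Adjustment of label in the environment	ENV	label	true	NIC
Adjustment of area in the environment	ENV	area	true	RCD
Adjustment of home in the environment	ENV	home	true	SNOMED_US
Adjustment of classroom in the environment	ENV	classroom	true	CHV
Adjustment of playground in the environment	ENV	playground	false	
Adjustment of environment in the environment	ENV	environment	false	
Adjustment of structure in the environment	ENV	structure	false	
Adjustment of arrangement in the environment	ENV	arrangement	false	
Adjustment of distraction in the environment	ENV	distraction	false	
Adjustment of barrier in the environment	ENV	barrier	false	
Adjustment of access in the environment	ENV	access	false	
Adjustment of equipment in the environment	ENV	equipment	false	
Adjustment of tool in the environment	ENV	tool	false	
Adjustment of layout in the environment	ENV	layout	false	
Adjustment of neighbor in the environment	ENV	neighbor	false	
Adjustment of transport in the environment	ENV	transport	false	
Promotion of child confidence	SELF	confidence,praise,encourage	true	NOC
Promotion of child proud	SELF	proud,esteem,belief	true	PSY
Promotion of child identity	SELF	identity,motivation,emotion	true	NIC
Promotion of child calm	SELF	calm,comfort,reassure	true	RCD
Promotion of child affirmation	SELF	affirmation,strength,worth	true	SNOMED_US
Promotion of child pride	SELF	pride,courage,positive	true	CHV
Promotion of child mindset	SELF	mindset,resilience,feel	true	NOC
Promotion of child mood	SELF	mood,anxiety,stress	true	PSY
Promotion of child relax	SELF	relax,breathe,patience	true	NIC
Promotion of child trust	SELF	trust,independence,ownership	false	
Promotion of child responsibility	SELF	responsibility,maturity	false	
Promotion of child awareness	SELF	awareness,reflection	false	
Promotion of child journal	SELF	journal,talk	false	
Promotion of child listen	SELF	listen,support	false	
Promotion of child empathy	SELF	empathy,kindness	false	
Offering choice based on child preference	PREF	choice,choose,favorite,interest	true	RCD
Offering preference based on child preference	PREF	preference,like,enjoy,fun	true	SNOMED_US
Offering hobby based on child preference	PREF	hobby,passion,option,select	true	CHV
Offering want based on child preference	PREF	want,wish,desire,pick	true	NOC
Offering theme based on child preference	PREF	theme,game,toy	true	PSY
Offering sport based on child preference	PREF	sport,art,craft	true	NIC
Offering dance based on child preference	PREF	dance,song,animal	true	RCD
Offering color based on child preference	PREF	color,food,snack	true	SNOMED_US
Offering reward based on child preference	PREF	reward,motivator,topic	true	CHV
Offering character based on child preference	PREF	character,style,activity	false	
Offering variety based on child preference	PREF	variety,menu,vote	false	
Offering decide based on child preference	PREF	decide,opinion,taste	false	
Training of practice for activity competence	COMP	practice,skill,teach,step,instruction,repeat,drill	true	NOC
Training of master for activity competence	COMP	master,learn,train,coach,demonstrate,model,guide	true	PSY
Training of task for activity competence	COMP	task,goal,progress,level,challenge,improve,ability	true	NIC
Training of competence for activity competence	COMP	competence,technique,exercise,lesson,tutor,homework,breakdown	true	RCD
Training of sequence for activity competence	COMP	sequence,attempt,effort,feedback,correction,milestone	true	SNOMED_US
Training of speed for activity competence	COMP	speed,accuracy,endurance,coordination,balance,memory	false	
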