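domain,canonical_term,variant,fuzzy_eligible
blunted_affect,flat affect,flat affect,true
blunted_affect,flat affect,flattened affect,true
blunted_affect,flat affect,affect flat,true
blunted_affect,blunted affect,blunted affect,true
blunted_affect,blunted affect,blunting of affect,true
blunted_affect,blunted affect,restricted affect,true
blunted_affect,poor eye contact,poor eye contact,true
blunted_affect,poor eye contact,avoids eye contact,true
avolition,avolition,avolition,true
avolition,avolition,lack of volition,true
avolition,withdrawn,withdrawn,true
avolition,poor hygiene,poor hygiene,true
avolition,no motivation,no motivation,true
avolition,no motivation,lack of motivation,true
avolition,no motivation,decreased motivation,true
avolition,poor grooming,poor grooming,true
avolition,loss of interest in activities,loss of interest in activities,true
avolition,passivity,passivity,true
alogia,alogia,alogia,true
alogia,no response,no response,true
alogia,poverty of speech,poverty of speech,true
alogia,short answers,short answers,true
alogia,not spontaneous,not spontaneous,true
alogia,brief answers,brief answers,true
alogia,minimal response,minimal response,true
asociality,asociality,asociality,true
asociality,social withdrawal,social withdrawal,true
asociality,social withdrawal,socially withdrawn,true
asociality,no friends,no friends,false
asociality,few friends,few friends,false
anhedonia,anhedonia,anhedonia,true
anhedonia,loss of interest,loss of interest,true
anhedonia,apathetic,apathetic,true
anhedonia,apathy,apathy,true
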