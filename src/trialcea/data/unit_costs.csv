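item,unit_cost,unit_description
hospital_outpatient,114.50,Per hospital outpatient clinic visit
a_and_e,140.59,Per accident & emergency attendance
other_outpatient,115.88,Per other outpatient visit
gp_surgery,44.00,Per GP patient contact at the practice (11.7 min)
gp_home,88.92,Per GP home visit (11.4 min plus 12 min travel)
nurse_surgery,11.11,Per 15.5 min practice-nurse appointment
other_primary_care,33.30,Per other primary care visit
physiotherapist,38.00,Per physiotherapist hour
occupational_therapist,44.00,Per occupational therapist hour
other_community_care,66.57,Per other community care visit
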