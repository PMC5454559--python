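participant_id,age,carer_age,affected_side,time_since_stroke_months,computer_experience,walking_aid
1,63,57,R hemi,13,++,None
2,73,73,L hemi,18,+,Frame or tripod
3,45,44,R hemi,18,+++,None
4,60,60,L hemi,15,++,None
5,42,44,R hemi,12,++,None
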