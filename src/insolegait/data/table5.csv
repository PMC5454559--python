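participant_id,heel_affected_pct,heel_nonaffected_pct,balance_pct,speed_pct
1,0.7,-32.3,-7.4,23.8
2,-1.4,0.1,-9.1,17.5
3,29.0,-11.5,-15.8,1.5
4,5.4,-2.3,-14.2,0.7
5,10.5,-3.7,4.0,5.5
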