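name,events_ctrl,n_ctrl,events_trt,n_trt,logor,variance,derivation
identical_arms,20,100,20,100,0.0,0.125,ln((20/80)/(20/80))=0; 1/20+1/80+1/20+1/80=0.125
modest_benefit,20,100,16,100,-0.2719337154836418,0.13690476190476192,ln((16/84)/(20/80)); 1/16+1/84+1/20+1/80
zero_cell_continuity,0,100,10,100,3.149330314516673,2.1162380677512203,"0.5 added to all four cells: (10.5,90.5) vs (0.5,100.5)"
strong_benefit,30,100,15,100,-0.8873031950009027,0.12605042016806722,ln((15/85)/(30/70)); 1/15+1/85+1/30+1/70
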