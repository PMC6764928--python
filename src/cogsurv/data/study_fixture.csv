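diagnosis,age_band,location,hemisphere,test_1,test_2,test_3,impairment_count_t0,pd_during_followup,end_reason
GBM,18-20,Frontal,Left,SAT,LF,SDC,3,False,completed_T24_no_PD
GBM,60-70,Parieto-occipital,Right,SAT,VEM,SDC,2,True,PD
AA,30-40,Frontal,Left,DSF,LF,SAT,1,False,completed_T24_no_PD
GBM,60-70,Occipital,Left,VIM,DSB,DSF,0,True,PD
GBM,50-60,Occipital,Right,SDC,CPT,FTT,2,True,PD
GBM,50-60,Fronto-parietal,Right,SAT,VIM,VEM,1,True,PD
GBM,40-50,Frontal,Right,SAT,CPT,FTT,2,True,PD
GBM,60-70,Parietal,Right,CPT,SAT,VEM,3,True,PD
GBM,60-70,Occipital,Right,VIM,SAT,VEM,3,True,PD
GBM,40-50,Frontal,Left,FTT,CPT,SAT,0,True,PD
GBM,50-60,Parieto-occipital,Left,SAT,CPT,SDC,1,False,dropout
GBM,50-60,Parietal,Left,SAT,VIM,FTT,3,True,PD
GBM,50-60,Parieto-occipital,Right,FTT,CPT,SDC,3,False,dropout
AA,30-40,Frontal,Right,VIM,VEM,LF,0,False,completed_T24_no_PD
GBM,60-70,Temporo-parietal,Left,FTT,SAT,Stroop,0,True,PD
GBM,70-80,Parietal,Right,FTT,SAT,Stroop,2,True,PD
GBM,50-60,Frontal,Right,FTT,VIM,DSF,0,True,PD
GBM,50-60,Occipital,Right,VEM,VIM,LF,2,True,PD
GBM,50-60,Temporo-parietal,Left,FTT,VEM,Stroop,0,True,PD
GBM,30-40,Occipital,Right,FTT,DSF,SDC,2,False,dropout
GBM,70-80,Temporal,Right,Stroop,SAT,VIM,0,True,PD
GBM,50-60,Occipital,Right,VIM,Stroop,FTT,1,False,active_at_end
GBM,50-60,Mesiotemporal,Left,FTT,LF,SDC,3,False,active_at_end
AA,50-60,Temporal,Right,SAT,SDC,DSB,3,False,active_at_end
AA,20-30,Parieto-occipital,Left,FTT,VEM,DSB,2,False,active_at_end
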