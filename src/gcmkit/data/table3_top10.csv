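rank,statement_id,text,cluster_label,mean,sd
1,17,Mutual respect between clinician and client,Interaction client clinician,3.90,0.30
2,15,Trust between client and clinician,Interaction client clinician,3.86,0.43
3,57,A good match between client and clinician,Interaction client clinician,3.69,0.65
4,75,Discussing practical tools on how to cope with depression,Clinician's adherence to good practice,3.69,0.53
5,6,Commitment from the client,The client,3.66,0.66
6,48,Evaluating the triggers of the depression,Clinician's adherence to good practice,3.66,0.48
7,55,The possibility to change clinician if there is no appropriate match,Treatment organisation,3.66,0.54
8,19,An open attitude from the clinician,The clinician,3.62,0.67
9,26,A therapist with patience,The clinician,3.59,0.77
10,37,Discussing the diagnosis with the client,Clinician's adherence to good practice,3.59,0.49
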