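statement_id,text,cluster_id,cluster_label,mean,sd
1,the client accepting the diagnosis,1,The client,3.55,0.62
2,activation of the client,1,The client,3.41,0.67
3,activities that help the client reconnect to their bodies,9,Supporting activities,2.86,0.74
4,"helping the client find back interests such as gardening, cooking together, pottery or other creative activities",10,Supportive work and home life,3.14,0.87
5,capacity from the client to confront their own weaknesses,1,The client,3.17,0.75
6,commitment from the client,1,The client,3.66,0.66
7,Resilience from the client,1,The client,2.97,0.85
8,a motivated client,1,The client,3.54,0.68
9,That the client has insight that they are ill,1,The client,3.31,0.79
10,opportunity for the client to focus on themselves,9,Supporting activities,3.36,0.89
11,"that the client has (prospect of) work, paid or voluntarily",10,Supportive work and home life,2.59,0.89
12,that the client has (prospect of) financial stability,10,Supportive work and home life,3.00,0.91
13,giving the client a clear role in treatment,2,Treatment process,3.28,0.78
14,a client that adheres to agreements made during treatment,1,The client,3.48,0.72
15,trust between client and clinician,5,Interaction client clinician,3.86,0.43
16,a therapist that tells the client when they do not know something,4,The clinician,3.17,0.79
17,mutual respect between clinician and client,5,Interaction client clinician,3.90,0.30
18,an empathic therapist,4,The clinician,3.41,0.72
19,an open attitude from the clinician,4,The clinician,3.62,0.67
20,vulnerability from the clinician,4,The clinician,2.36,0.93
21,knowledge through their own experience from clinician,4,The clinician,2.24,1.13
22,self-reflection from the clinician,4,The clinician,3.14,0.86
23,well-educated clinician(s),4,The clinician,3.55,0.72
24,a therapist who has clinical experience with treating clients,4,The clinician,3.21,0.89
25,flexibility from the therapist,4,The clinician,3.24,0.77
26,a therapist with patience,4,The clinician,3.59,0.77
27,a clinician who is not focused on the computer during treatment,4,The clinician,3.24,0.93
28,cultural understanding from the therapist towards the client,4,The clinician,3.24,0.90
29,good communication between employees of the clinician's office,5,Interaction client clinician,2.52,1.04
30,contact between the clinician and client's other health care providers,6,Clinician's adherence to good practice,2.93,0.83
31,a multidisciplinary team,3,Treatment organisation,2.90,0.84
32,that the therapist is part of a clinical network to rely on their expertise and treatment options,3,Treatment organisation,2.90,0.96
33,communication about expectations of medication with the client,7,Drug treatment,3.55,0.62
34,good communication about treatment steps,3,Treatment organisation,3.52,0.56
35,frequent contact during all steps of treatment,2,Treatment process,3.34,0.71
36,treatment for other diagnoses in combination with depression treatment,6,Clinician's adherence to good practice,3.14,0.86
37,discussing the diagnosis with the client,6,Clinician's adherence to good practice,3.59,0.49
38,good diagnostics,3,Treatment organisation,3.55,0.77
39,low severity of depression prior to treatment (i.e. having a mild depression before treatment),8,Pre-condition,1.79,1.03
40,high severity of depression prior to treatment (i.e. having a severe depression before treatment),8,Pre-condition,1.90,1.09
41,time-off from employer to receive treatment,10,Supportive work and home life,2.97,1.00
42,having an understanding employer,10,Supportive work and home life,3.03,0.93
43,decreasing stress in the client's home environment,10,Supportive work and home life,3.38,0.72
44,a safe home environment,10,Supportive work and home life,3.45,0.72
45,as little stigmatization as possible from the client's environment,10,Supportive work and home life,3.28,0.78
46,regular critical evaluation of the need to take or not take certain medication,7,Drug treatment,3.55,0.56
47,evaluating the cause of the depression,6,Clinician's adherence to good practice,3.38,0.81
48,evaluating the triggers of the depression,6,Clinician's adherence to good practice,3.66,0.48
49,exercise (a client that physically exercises),9,Supporting activities,3.10,0.88
50,clear goals for the client,2,Treatment process,3.24,0.67
51,evaluating goals,2,Treatment process,3.31,0.65
52,professional support in the home environment,10,Supportive work and home life,2.59,1.07
53,hope for improvement from the client,1,The client,3.21,0.85
54,involving loved ones,10,Supportive work and home life,2.45,0.97
55,the possibility to change clinician if there is no appropriate match,3,Treatment organisation,3.66,0.54
56,timely evaluation of the match between client and clinician,5,Interaction client clinician,3.28,0.69
57,a good match between client and clinician,5,Interaction client clinician,3.69,0.65
58,monitoring (checking up how the client is doing),3,Treatment organisation,3.31,0.79
59,a choice of treatments when the current treatment does not work for or fit with the client,2,Treatment process,3.38,0.72
60,reconnection of the client to nature,9,Supporting activities,2.24,1.01
61,informing about different therapy options,6,Clinician's adherence to good practice,3.21,0.85
62,trying out different therapies,2,Treatment process,2.76,0.86
63,attention for the client's physical health,6,Clinician's adherence to good practice,3.31,0.83
64,discussing activities and things that the client can take energy from in their daily life,9,Supporting activities,3.31,0.70
65,paying attention during treatment to things that are nice instead of just symptoms,6,Clinician's adherence to good practice,2.83,0.83
66,progress,1,The client,3.34,0.71
67,keeping to treatment guidelines and protocol,2,Treatment process,2.55,0.97
68,involving close family members or friends in psychoeducation,10,Supportive work and home life,2.38,0.93
69,adequate psychoeducation for the client,6,Clinician's adherence to good practice,2.96,0.91
70,a client who reads about depression,9,Supporting activities,2.07,0.87
71,a relapse prevention plan,6,Clinician's adherence to good practice,3.38,0.85
72,the client making their own treatment choices,2,Treatment process,3.21,1.00
73,a safe space to talk about side effects,7,Drug treatment,3.52,0.77
74,a stable social safety network around the client,10,Supportive work and home life,3.24,0.82
75,discussing practical tools on how to cope with depression,6,Clinician's adherence to good practice,3.69,0.53
76,addressing possible redirection of feelings in the communication between clinician and client (transference) in a safe way during treatment,5,Interaction client clinician,3.28,0.69
77,no predetermined end date of the treatment,2,Treatment process,2.90,1.03
78,continuity between treatments,2,Treatment process,3.52,0.68
79,a short waiting time,6,Clinician's adherence to good practice,3.41,0.89
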