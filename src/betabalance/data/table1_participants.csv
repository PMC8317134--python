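id,gender,age,minibest,tug_single,tug_dual,dti_s_printed,step_threshold
C01,M,71,28,6.8,6.78,0.02,18
C02,M,70,27,8.4,7.62,0.78,13
C03,F,60,21,6.4,9.7,-3.3,6
C04,F,78,20,10.45,10.96,-0.51,11
C05,M,76,23,11.14,11.32,-0.18,15
C06,F,80,22,7,12.32,-5.32,7.5
C07,M,51,26,7.4,8.2,-0.8,13
C08,F,65,24,5.9,8,-2.1,11
C09,F,70,20,11.2,11.84,-0.64,14
C10,F,61,26,9.19,10.28,-1.09,12
C13,F,75,24,10.2,11.4,-1.2,14
C14,F,66,25,10.33,11.51,-1.18,12
C15,F,78,22,9.07,10.91,-1.84,8.5
C16,F,59,24,6.97,8.25,-1.28,9
C18,F,73,24,7.52,10.19,-2.67,7
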