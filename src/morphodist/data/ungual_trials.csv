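analysis,removal,method,icp,reference,mean_distance,sd_distance,n_points
1,no,C2M,no,MCII,1.040397,1.121258,34928
1,no,C2M,yes,MCII,0.986824,1.022618,34928
1,no,C2C,no,MCII,1.075497,1.104225,34928
1,no,C2C,yes,MCII,1.016886,1.010965,34928
2,yes,C2M,no,MCII,0.927858,0.647785,14050
2,yes,C2M,yes,MCII,0.668333,0.559787,14050
2,yes,C2C,no,MCII,0.974374,0.613839,14050
2,yes,C2C,yes,MCII,0.771036,0.511375,14050
3,yes,C2M,no,MCI,2.130718,1.874513,12780
3,yes,C2M,yes,MCI,1.634286,1.351795,12780
3,yes,C2C,no,MCI,2.231208,1.814349,12780
3,yes,C2C,yes,MCI,1.739542,1.294163,12780
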