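# final_design_synthetic.csv
#
# SYNTHETIC stand-in for the study's chosen school-year stepped wedge
# configuration: selected by this package's own two-stage shortlist over the
# 256 enumerated candidates (closed-form power band, then lowest absolute
# percentage bias under a 4-min seasonal trend at reduced replicates, then
# school-burden tie-breaks).  It is a reconstruction of the selection
# procedure's outcome, not a transcription of any external artefact.
#
# States: C/c measured/unmeasured control, X implementation (one term,
# unmeasured), I/i measured/unmeasured intervention.  Period 0 is the
# baseline occasion in the previous school year; periods 1-6 are Terms 1-6.
sequence,schools,p0:t0:m-3:y6,p1:t1:m1:y10,p2:t2:m2.5:y11.5,p3:t3:m4.5:y1.5,p4:t4:m6:y3,p5:t5:m7.5:y4.5,p6:t6:m9:y6#baseline=0
0,3,C,X,I,I,i,i,I
1,3,C,C,X,I,i,I,i
2,3,C,c,C,X,I,I,i
3,3,C,c,C,C,X,I,i
4,3,C,C,c,c,C,X,I
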