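name	sequence	orientation	gene	ref_position
pmoC374	AGCARGACGGYACNTGGC	forward	pmoC	374
pmoA189	GGNGACTGGGACTTCTGG	forward	pmoA	189
pmoA344	ANGTCCAHCCCCAGAAGT	reverse	pmoA	344
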