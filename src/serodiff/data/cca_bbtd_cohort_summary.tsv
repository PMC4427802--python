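variable	stat	cca	bbtd	reported_p
n	count	19	17	
sex_male	count	10	10	0.085
sex_female	count	9	7	
age	mean	60.9	52.6	0.285
age	sd	13	13	
cea	median	9.87	8.70	0.711
cea	min	1.47	0.62	
cea	max	410.40	118.30	
ca19_9	median	4355.50	48.03	0.015
ca19_9	min	0.60	0.60	
ca19_9	max	10000	10000	
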