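description	share_pct	category	unit_price
Always Ultra normal plus with wings 14s	3.62	ST	0.13
Always Ultra night wing towels 10s	2.99	ST	0.18
Always Ultra long plus with wings 12s	2.96	ST	0.15
Tampax Compak tampons regular 20s	2.05	T	0.13
Bodyform Ultra normal wing towels 14s	2.05	ST	0.10
non app tampons regular 16s	1.78	T	0.07
Always Ultra normal 16s	1.75	ST	0.11
Ultra towels normal 16s	1.60	ST	0.07
Ultra towels normal wing 14s	1.60	ST	0.07
Tampax Compak tampons super 20s	1.57	T	0.13
non app tampons super 16s	1.48	T	0.07
Ultra towels night wing 10s	1.44	ST	0.11
Lil-Lets tampons super plus extra 14s	1.38	T	0.19
Ultra towels super wing 12s	1.32	ST	0.09
applicator tampons regular 12s	1.30	T	0.09
Bodyform Ultra goodnight wing towels 10s	1.28	ST	0.15
Tampax Compak active tampons regular 20s	1.20	T	0.33
Ultra towels super 14s	1.19	ST	0.08
Tampax Blue Box Regular 12S	1.19	T	0.09
Bodyform Ultra super wing towels 12s	1.19	ST	0.12
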