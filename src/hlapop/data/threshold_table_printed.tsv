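# Published allele-frequency significance thresholds (%) below which the
# 95% confidence interval contains zero, by sample size N and sampling model:
# I standard normal two-tail, II normal one-tail, III exact binomial.
# N<TAB>model_I<TAB>model_II<TAB>model_III
30	6.25	4.43	4.85
50	3.85	2.75	2.95
100	1.96	1.37	1.48
150	1.32	0.92	1.00
200	0.99	0.69	0.75
500	0.39	0.28	0.30
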