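label	weight_loss_pct	weight_loss_se	cellulose_loss_pct	cellulose_loss_se	holocellulose_loss_pct	holocellulose_loss_se	lignin_loss_pct	lignin_loss_se	cellulose_yield_pct	cellulose_yield_se	holocellulose_yield_pct	holocellulose_yield_se
Control	ND	ND	ND	ND	ND	ND	ND	ND	11.1	0.1	10.5	0.1
Day 4	0	1.9	0	1.8	0	2.0	2.4	1.8	19.6	1.0	16.4	0.6
Day 10	10.7	0.1	10.1	0.1	10.3	0.1	18.6	2.2	23.6	0.4	20.9	0.3
Day 15	19.6	1.2	17.4	1.2	15.8	1.3	36.2	1.0	35.2	1.5	30.0	0.3
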