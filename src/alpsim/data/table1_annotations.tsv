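subject	epoch_1	epoch_2	epoch_3	epoch_4	epoch_5	epoch_6	epoch_7	epoch_8	epoch_9	epoch_10	epoch_11	epoch_12	epoch_13	epoch_14	epoch_15	epoch_16	epoch_17
sub-01	0	1	1	1	1	1	1	N	N	1	1	1	1	1	1	1	N
sub-02	0	1	1	1	1	1	1	1	1	1	N	N	N	N	N	N	N
sub-03	0	1	1	1	1	1	1	1	N	N	N	N	N	1	1	1	N
sub-04	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
sub-05	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
sub-06	0	1	1	1	1	1	1	1	1	N	0	N	0	0	N	0	1
sub-07	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
sub-08	0	1	1	1	1	1	1	1	1	1	N	1	1	1	1	1	1
sub-09	0	1	1	1	1	1	1	1	N	N	N	N	N	N	1	1	1
sub-10	0	0	0	0	N	0	N	N	0	0	0	0	0	N	1	1	1
sub-11	0	N	N	1	1	N	1	1	1	1	N	1	1	N	N	N	N
sub-12	0	N	1	1	1	0	N	N	N	0	N	N	1	1	1	1	N
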