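construct	donor_type	pool_id	n_founders	positive	g0_survivors_total
190-perfect	plasmid	190-perfect-P01	20	true	271
190-perfect	plasmid	190-perfect-P02	20	true	271
190-perfect	plasmid	190-perfect-P03	20	true	271
190-perfect	plasmid	190-perfect-P04	20	true	271
190-perfect	plasmid	190-perfect-P05	20	true	271
190-perfect	plasmid	190-perfect-P06	20	true	271
190-perfect	plasmid	190-perfect-P07	20	true	271
190-perfect	plasmid	190-perfect-P08	20	true	271
190-perfect	plasmid	190-perfect-P09	20	true	271
190-perfect	plasmid	190-perfect-P10	20	true	271
190-perfect	plasmid	190-perfect-P11	20	true	271
190-perfect	plasmid	190-perfect-P12	20	true	271
190-perfect	plasmid	190-perfect-P13	20	true	271
64+234-perfect	plasmid	64+234-perfect-P01	20	true	355
64+234-perfect	plasmid	64+234-perfect-P02	20	true	355
64+234-perfect	plasmid	64+234-perfect-P03	20	true	355
64+234-perfect	plasmid	64+234-perfect-P04	20	true	355
64+234-perfect	plasmid	64+234-perfect-P05	20	true	355
64+234-perfect	plasmid	64+234-perfect-P06	20	true	355
64+234-perfect	plasmid	64+234-perfect-P07	20	true	355
64+234-perfect	plasmid	64+234-perfect-P08	20	true	355
64+234-perfect	plasmid	64+234-perfect-P09	20	false	355
64+234-perfect	plasmid	64+234-perfect-P10	20	false	355
64+234-perfect	plasmid	64+234-perfect-P11	20	false	355
64+234-perfect	plasmid	64+234-perfect-P12	20	false	355
64+234-perfect	plasmid	64+234-perfect-P13	20	false	355
64+234-perfect	plasmid	64+234-perfect-P14	20	false	355
64+234-perfect	plasmid	64+234-perfect-P15	20	false	355
64+234-perfect	plasmid	64+234-perfect-P16	20	false	355
64+234-perfect	plasmid	64+234-perfect-P17	20	false	355
234-recoded	plasmid	234-recoded-P01	20	true	339
234-recoded	plasmid	234-recoded-P02	20	true	339
234-recoded	plasmid	234-recoded-P03	20	true	339
234-recoded	plasmid	234-recoded-P04	20	true	339
234-recoded	plasmid	234-recoded-P05	20	true	339
234-recoded	plasmid	234-recoded-P06	20	true	339
234-recoded	plasmid	234-recoded-P07	20	true	339
234-recoded	plasmid	234-recoded-P08	20	true	339
234-recoded	plasmid	234-recoded-P09	20	false	339
234-recoded	plasmid	234-recoded-P10	20	false	339
234-recoded	plasmid	234-recoded-P11	20	false	339
234-recoded	plasmid	234-recoded-P12	20	false	339
234-recoded	plasmid	234-recoded-P13	20	false	339
234-recoded	plasmid	234-recoded-P14	20	false	339
234-recoded	plasmid	234-recoded-P15	20	false	339
234-recoded	plasmid	234-recoded-P16	20	false	339
190-recoded	plasmid	190-recoded-P01	20	true	184
190-recoded	plasmid	190-recoded-P02	20	true	184
190-recoded	plasmid	190-recoded-P03	20	true	184
190-recoded	plasmid	190-recoded-P04	20	false	184
190-recoded	plasmid	190-recoded-P05	20	false	184
190-recoded	plasmid	190-recoded-P06	20	false	184
190-recoded	plasmid	190-recoded-P07	20	false	184
190-recoded	plasmid	190-recoded-P08	20	false	184
190-recoded	plasmid	190-recoded-P09	20	false	184
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P01	20	true	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P02	20	true	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P03	20	false	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P04	20	false	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P05	20	false	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P06	20	false	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P07	20	false	174
190-recoded-ssDNA	ssDNA	190-recoded-ssDNA-P08	20	false	174
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P01	20	true	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P02	20	true	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P03	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P04	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P05	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P06	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P07	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P08	20	false	184
190-recoded-BTN-dsDNA	BTN-dsDNA	190-recoded-BTN-dsDNA-P09	20	false	184
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P01	20	true	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P02	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P03	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P04	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P05	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P06	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P07	20	false	178
190-recoded-BTN-ssDNA	BTN-ssDNA	190-recoded-BTN-ssDNA-P08	20	false	178
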