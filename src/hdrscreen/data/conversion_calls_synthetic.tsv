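event_id	pool_id	construct	span_lo	span_hi	offset	state
ev01	RP-P1	190-recoded	-900	350	-850	wildtype
ev01	RP-P1	190-recoded	-900	350	-725	wildtype
ev01	RP-P1	190-recoded	-900	350	-600	wildtype
ev01	RP-P1	190-recoded	-900	350	-450	wildtype
ev01	RP-P1	190-recoded	-900	350	-319	wildtype
ev01	RP-P1	190-recoded	-900	350	-220	donor
ev01	RP-P1	190-recoded	-900	350	-150	donor
ev01	RP-P1	190-recoded	-900	350	-94	donor
ev01	RP-P1	190-recoded	-900	350	-60	donor
ev01	RP-P1	190-recoded	-900	350	16	wildtype
ev01	RP-P1	190-recoded	-900	350	75	wildtype
ev01	RP-P1	190-recoded	-900	350	130	wildtype
ev01	RP-P1	190-recoded	-900	350	220	wildtype
ev01	RP-P1	190-recoded	-900	350	310	wildtype
ev02	RP-P2	190-recoded	-900	350	-850	wildtype
ev02	RP-P2	190-recoded	-900	350	-725	wildtype
ev02	RP-P2	190-recoded	-900	350	-600	wildtype
ev02	RP-P2	190-recoded	-900	350	-450	wildtype
ev02	RP-P2	190-recoded	-900	350	-319	wildtype
ev02	RP-P2	190-recoded	-900	350	-220	wildtype
ev02	RP-P2	190-recoded	-900	350	-150	wildtype
ev02	RP-P2	190-recoded	-900	350	-94	donor
ev02	RP-P2	190-recoded	-900	350	-60	donor
ev02	RP-P2	190-recoded	-900	350	16	wildtype
ev02	RP-P2	190-recoded	-900	350	75	wildtype
ev02	RP-P2	190-recoded	-900	350	130	wildtype
ev02	RP-P2	190-recoded	-900	350	220	wildtype
ev02	RP-P2	190-recoded	-900	350	310	wildtype
ev03	RP-P3	190-recoded	-900	350	-850	wildtype
ev03	RP-P3	190-recoded	-900	350	-725	wildtype
ev03	RP-P3	190-recoded	-900	350	-600	wildtype
ev03	RP-P3	190-recoded	-900	350	-450	wildtype
ev03	RP-P3	190-recoded	-900	350	-319	wildtype
ev03	RP-P3	190-recoded	-900	350	-220	wildtype
ev03	RP-P3	190-recoded	-900	350	-150	wildtype
ev03	RP-P3	190-recoded	-900	350	-94	wildtype
ev03	RP-P3	190-recoded	-900	350	-60	wildtype
ev03	RP-P3	190-recoded	-900	350	16	donor
ev03	RP-P3	190-recoded	-900	350	75	donor
ev03	RP-P3	190-recoded	-900	350	130	wildtype
ev03	RP-P3	190-recoded	-900	350	220	wildtype
ev03	RP-P3	190-recoded	-900	350	310	wildtype
ev04	RP-P4	190-recoded	-900	350	-850	wildtype
ev04	RP-P4	190-recoded	-900	350	-725	wildtype
ev04	RP-P4	190-recoded	-900	350	-600	wildtype
ev04	RP-P4	190-recoded	-900	350	-450	wildtype
ev04	RP-P4	190-recoded	-900	350	-319	wildtype
ev04	RP-P4	190-recoded	-900	350	-220	wildtype
ev04	RP-P4	190-recoded	-900	350	-150	wildtype
ev04	RP-P4	190-recoded	-900	350	-94	wildtype
ev04	RP-P4	190-recoded	-900	350	-60	wildtype
ev04	RP-P4	190-recoded	-900	350	16	wildtype
ev04	RP-P4	190-recoded	-900	350	75	wildtype
ev04	RP-P4	190-recoded	-900	350	130	wildtype
ev04	RP-P4	190-recoded	-900	350	220	wildtype
ev04	RP-P4	190-recoded	-900	350	310	wildtype
ev05	RP-P5	190-recoded	-900	350	-850	wildtype
ev05	RP-P5	190-recoded	-900	350	-725	donor
ev05	RP-P5	190-recoded	-900	350	-600	donor
ev05	RP-P5	190-recoded	-900	350	-450	donor
ev05	RP-P5	190-recoded	-900	350	-319	donor
ev05	RP-P5	190-recoded	-900	350	-220	donor
ev05	RP-P5	190-recoded	-900	350	-150	donor
ev05	RP-P5	190-recoded	-900	350	-94	donor
ev05	RP-P5	190-recoded	-900	350	-60	donor
ev05	RP-P5	190-recoded	-900	350	16	donor
ev05	RP-P5	190-recoded	-900	350	75	wildtype
ev05	RP-P5	190-recoded	-900	350	130	wildtype
ev05	RP-P5	190-recoded	-900	350	220	wildtype
ev05	RP-P5	190-recoded	-900	350	310	wildtype
ev06	RC-P1	234-recoded	-350	330	-319	wildtype
ev06	RC-P1	234-recoded	-350	330	-260	wildtype
ev06	RC-P1	234-recoded	-350	330	-190	wildtype
ev06	RC-P1	234-recoded	-350	330	-140	donor
ev06	RC-P1	234-recoded	-350	330	-94	donor
ev06	RC-P1	234-recoded	-350	330	-60	donor
ev06	RC-P1	234-recoded	-350	330	-30	donor
ev06	RC-P1	234-recoded	-350	330	52	wildtype
ev06	RC-P1	234-recoded	-350	330	88	wildtype
ev06	RC-P1	234-recoded	-350	330	149	wildtype
ev06	RC-P1	234-recoded	-350	330	210	wildtype
ev06	RC-P1	234-recoded	-350	330	280	wildtype
ev07	RC-P2	234-recoded	-350	330	-319	wildtype
ev07	RC-P2	234-recoded	-350	330	-260	wildtype
ev07	RC-P2	234-recoded	-350	330	-190	wildtype
ev07	RC-P2	234-recoded	-350	330	-140	wildtype
ev07	RC-P2	234-recoded	-350	330	-94	wildtype
ev07	RC-P2	234-recoded	-350	330	-60	wildtype
ev07	RC-P2	234-recoded	-350	330	-30	wildtype
ev07	RC-P2	234-recoded	-350	330	52	donor
ev07	RC-P2	234-recoded	-350	330	88	donor
ev07	RC-P2	234-recoded	-350	330	149	wildtype
ev07	RC-P2	234-recoded	-350	330	210	wildtype
ev07	RC-P2	234-recoded	-350	330	280	wildtype
ev08	RC-P3	234-recoded	-350	330	-319	wildtype
ev08	RC-P3	234-recoded	-350	330	-260	wildtype
ev08	RC-P3	234-recoded	-350	330	-190	wildtype
ev08	RC-P3	234-recoded	-350	330	-140	wildtype
ev08	RC-P3	234-recoded	-350	330	-94	wildtype
ev08	RC-P3	234-recoded	-350	330	-60	donor
ev08	RC-P3	234-recoded	-350	330	-30	donor
ev08	RC-P3	234-recoded	-350	330	52	wildtype
ev08	RC-P3	234-recoded	-350	330	88	wildtype
ev08	RC-P3	234-recoded	-350	330	149	wildtype
ev08	RC-P3	234-recoded	-350	330	210	wildtype
ev08	RC-P3	234-recoded	-350	330	280	wildtype
ev09	RC-P4	234-recoded	-350	330	-319	wildtype
ev09	RC-P4	234-recoded	-350	330	-260	wildtype
ev09	RC-P4	234-recoded	-350	330	-190	wildtype
ev09	RC-P4	234-recoded	-350	330	-140	wildtype
ev09	RC-P4	234-recoded	-350	330	-94	wildtype
ev09	RC-P4	234-recoded	-350	330	-60	wildtype
ev09	RC-P4	234-recoded	-350	330	-30	wildtype
ev09	RC-P4	234-recoded	-350	330	52	wildtype
ev09	RC-P4	234-recoded	-350	330	88	wildtype
ev09	RC-P4	234-recoded	-350	330	149	wildtype
ev09	RC-P4	234-recoded	-350	330	210	wildtype
ev09	RC-P4	234-recoded	-350	330	280	wildtype
ev10	RC-P5	234-recoded	-350	330	-319	wildtype
ev10	RC-P5	234-recoded	-350	330	-260	wildtype
ev10	RC-P5	234-recoded	-350	330	-190	wildtype
ev10	RC-P5	234-recoded	-350	330	-140	wildtype
ev10	RC-P5	234-recoded	-350	330	-94	donor
ev10	RC-P5	234-recoded	-350	330	-60	donor
ev10	RC-P5	234-recoded	-350	330	-30	donor
ev10	RC-P5	234-recoded	-350	330	52	donor
ev10	RC-P5	234-recoded	-350	330	88	donor
ev10	RC-P5	234-recoded	-350	330	149	donor
ev10	RC-P5	234-recoded	-350	330	210	wildtype
ev10	RC-P5	234-recoded	-350	330	280	wildtype
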