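individual	sample_id	method	call	replicate_index
INDV-1	STR18F-01	sanger	x/x	0
INDV-1	STR18F-01	ngs	+/+	0
INDV-1	STR18F-01	aspcr	+/+	0
INDV-1	STR18F-25	sanger	+/+	0
INDV-1	STR18F-25	ngs	x/x	0
INDV-1	STR18F-25	aspcr	+/+	0
INDV-1	STR18F-75	sanger	+/+	0
INDV-1	STR18F-75	ngs	+/+	0
INDV-1	STR18F-75	aspcr	+/+	0
INDV-1	SIM19F-14	sanger	+/+	0
INDV-1	SIM19F-14	ngs	+/+	0
INDV-1	SIM19F-14	aspcr	+/+	0
INDV-2	STR18-02	sanger	+/m	0
INDV-2	STR18-02	ngs	x/x	0
INDV-2	STR18-02	aspcr	+/m	0
INDV-2	STR18-27	sanger	+/m	0
INDV-2	STR18-27	ngs	x/x	0
INDV-2	STR18-27	aspcr	+/m	0
INDV-2	STR18-49	sanger	+/m	0
INDV-2	STR18-49	ngs	x/x	0
INDV-2	STR18-49	aspcr	+/m	0
INDV-2	SIM19-09	sanger	x/x	0
INDV-2	SIM19-09	ngs	+/m	0
INDV-2	SIM19-09	aspcr	+/m	0
INDV-2	SIM19-29	sanger	+/m	0
INDV-2	SIM19-29	ngs	+/m	0
INDV-2	SIM19-29	aspcr	+/m	0
INDV-3	STRF18-04	sanger	+/m	0
INDV-3	STRF18-04	ngs	x/x	0
INDV-3	STRF18-04	aspcr	+/m	0
INDV-3	STRF18-19	sanger	+/m	0
INDV-3	STRF18-19	ngs	+/m	0
INDV-3	STRF18-19	aspcr	+/m	0
INDV-3	STRF18-21	sanger	+/m	0
INDV-3	STRF18-21	ngs	x/x	0
INDV-3	STRF18-21	aspcr	+/m	0
INDV-3	STRF18-43	sanger	+/m	0
INDV-3	STRF18-43	ngs	+/m	0
INDV-3	STRF18-43	aspcr	+/m	0
INDV-3	STRF18-56	sanger	+/m	0
INDV-3	STRF18-56	ngs	x/x	0
INDV-3	STRF18-56	aspcr	+/m	0
INDV-3	STRF18-57	sanger	x/x	0
INDV-3	STRF18-57	ngs	+/m	0
INDV-3	STRF18-57	aspcr	+/m	0
INDV-3	STRF18-58	sanger	x/x	0
INDV-3	STRF18-58	ngs	x/x	0
INDV-3	STRF18-58	aspcr	+/m	0
INDV-3	STRF18-81	sanger	+/+	0
INDV-3	STRF18-81	ngs	x/x	0
INDV-3	STRF18-81	aspcr	+/m	0
INDV-3	STRF18-81	aspcr	+/m	1
INDV-3	STRF18-81	aspcr	+/m	2
INDV-3	STRF18-81	aspcr	+/m	3
INDV-3	STRF18-92	sanger	+/m	0
INDV-3	STRF18-92	ngs	+/m	0
INDV-3	STRF18-92	aspcr	+/m	0
INDV-4	STRF18-07	sanger	m/m	0
INDV-4	STRF18-07	ngs	m/m	0
INDV-4	STRF18-07	aspcr	m/m	0
INDV-4	STRF18-20	sanger	m/m	0
INDV-4	STRF18-20	ngs	m/m	0
INDV-4	STRF18-20	aspcr	m/m	0
INDV-4	STRF18-26	sanger	m/m	0
INDV-4	STRF18-26	ngs	m/m	0
INDV-4	STRF18-26	aspcr	m/m	0
INDV-4	STRF18-41	sanger	m/m	0
INDV-4	STRF18-41	ngs	m/m	0
INDV-4	STRF18-41	aspcr	m/m	0
INDV-4	STRF18-46	sanger	x/x	0
INDV-4	STRF18-46	ngs	m/m	0
INDV-4	STRF18-46	aspcr	m/m	0
INDV-4	STRF18-61	sanger	m/m	0
INDV-4	STRF18-61	ngs	m/m	0
INDV-4	STRF18-61	aspcr	m/m	0
INDV-4	STRF18-84	sanger	m/m	0
INDV-4	STRF18-84	ngs	x/x	0
INDV-4	STRF18-84	aspcr	m/m	0
INDV-5	STRF18-09	sanger	x/x	0
INDV-5	STRF18-09	ngs	+/m	0
INDV-5	STRF18-09	aspcr	m/m	0
INDV-5	STRF18-09	aspcr	m/m	1
INDV-5	STRF18-09	aspcr	m/m	2
INDV-5	STRF18-09	aspcr	m/m	3
INDV-5	SIMF19-01	sanger	m/m	0
INDV-5	SIMF19-01	ngs	m/m	0
INDV-5	SIMF19-01	aspcr	m/m	0
INDV-6	STRF18-10	sanger	x/x	0
INDV-6	STRF18-10	ngs	x/x	0
INDV-6	STRF18-10	aspcr	m/m	0
INDV-6	STRF18-11	sanger	+/m	0
INDV-6	STRF18-11	ngs	+/m	0
INDV-6	STRF18-11	aspcr	+/m	0
INDV-6	STRF18-50	sanger	+/m	0
INDV-6	STRF18-50	ngs	+/m	0
INDV-6	STRF18-50	aspcr	+/m	0
INDV-6	STRF18-94	sanger	+/+	0
INDV-6	STRF18-94	ngs	x/x	0
INDV-6	STRF18-94	aspcr	+/m	0
INDV-6	STRF18-94	aspcr	+/m	1
INDV-6	STRF18-94	aspcr	+/m	2
INDV-6	STRF18-94	aspcr	+/m	3
INDV-7	STRF18-08	sanger	x/x	0
INDV-7	STRF18-08	ngs	x/x	0
INDV-7	STRF18-08	aspcr	m/m	0
INDV-8	STRF18-59	sanger	+/+	0
INDV-8	STRF18-59	ngs	x/x	0
INDV-8	STRF18-59	aspcr	+/+	0
INDV-9	STRF18-62	sanger	m/m	0
INDV-9	STRF18-62	ngs	m/m	0
INDV-9	STRF18-62	aspcr	x/x	0
INDV-10	STRF18-85	sanger	x/x	0
INDV-10	STRF18-85	ngs	x/x	0
INDV-10	STRF18-85	aspcr	+/m	0
INDV-11	SIM18T-103	sanger	+/m	0
INDV-11	SIM18T-103	ngs	x/x	0
INDV-11	SIM18T-103	aspcr	x/x	0
INDV-12	SIM19-08	sanger	+/m	0
INDV-12	SIM19-08	ngs	+/m	0
INDV-12	SIM19-08	aspcr	+/m	0
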