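sample_id	donor_id	timepoint	declared_sex	dataset_id	redkx_call
GSM155503	55	1	F	GSE6751	F
GSM155504	55	2	F	GSE6751	F
GSM155505	55	3	F	GSE6751	F
GSM155506	55	4	F	GSE6751	F
GSM155499	54	1	F	GSE6751	F
GSM155500	54	2	F	GSE6751	F
GSM155501	54	3	F	GSE6751	F
GSM155502	54	4	F	GSE6751	F
GSM155495	45	1	F	GSE6751	F
GSM155496	45	2	F	GSE6751	F
GSM155497	45	3	F	GSE6751	F
GSM155498	45	4	F	GSE6751	F
GSM155475	35	1	M	GSE6751	F
GSM155476	35	2	M	GSE6751	M
GSM155477	35	3	M	GSE6751	M
GSM155478	35	4	M	GSE6751	M
GSM155471	32	1	F	GSE6751	F
GSM155472	32	2	F	GSE6751	M
GSM155473	32	3	F	GSE6751	F
GSM155474	32	4	F	GSE6751	F
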