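probe_id	GSM155503	GSM155504	GSM155505	GSM155506	GSM155499	GSM155500	GSM155501	GSM155502	GSM155495	GSM155496	GSM155497	GSM155498	GSM155475	GSM155476	GSM155477	GSM155478	GSM155471	GSM155472	GSM155473	GSM155474
203290_at	28	23	10	28	33	49	28	26	45	59	32	59	1218	436	508	126	1235	420	1807	1128
213831_at	4182	4606	2412	4765	516	681	1073	914	8041	7619	6385	7062	42	1491	1751	113	32	1878	49	42
209728_at	48	72	24	21	985	1245	3142	2573	187	123	105	40	6444	231	200	5	8231	291	7332	7122
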