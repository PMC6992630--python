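immunoseq	imgt
TCRBV01-01	TRBV1
TCRBV02-01	TRBV2
TCRBV03-01	TRBV3-1
TCRBV04-01	TRBV4-1
TCRBV04-02	TRBV4-2
TCRBV04-03	TRBV4-3
TCRBV05-01	TRBV5-1
TCRBV05-04	TRBV5-4
TCRBV05-05	TRBV5-5
TCRBV05-06	TRBV5-6
TCRBV05-08	TRBV5-8
TCRBV06-01	TRBV6-1
TCRBV06-04	TRBV6-4
TCRBV06-05	TRBV6-5
TCRBV06-06	TRBV6-6
TCRBV07-02	TRBV7-2
TCRBV07-03	TRBV7-3
TCRBV07-06	TRBV7-6
TCRBV07-07	TRBV7-7
TCRBV07-08	TRBV7-8
TCRBV07-09	TRBV7-9
TCRBV09-01	TRBV9
TCRBV10-01	TRBV10-1
TCRBV10-02	TRBV10-2
TCRBV10-03	TRBV10-3
TCRBV11-01	TRBV11-1
TCRBV11-02	TRBV11-2
TCRBV11-03	TRBV11-3
TCRBV12-05	TRBV12-5
TCRBV13-01	TRBV13
TCRBV14-01	TRBV14
TCRBV15-01	TRBV15
TCRBV16-01	TRBV16
TCRBV18-01	TRBV18
TCRBV19-01	TRBV19
TCRBV20-01	TRBV20-1
TCRBV24-01	TRBV24-1
TCRBV25-01	TRBV25-1
TCRBV27-01	TRBV27
TCRBV28-01	TRBV28
TCRBV29-01	TRBV29-1
TCRBV30-01	TRBV30
TCRBJ01-01	TRBJ1-1
TCRBJ01-02	TRBJ1-2
TCRBJ01-03	TRBJ1-3
TCRBJ01-04	TRBJ1-4
TCRBJ01-05	TRBJ1-5
TCRBJ01-06	TRBJ1-6
TCRBJ02-01	TRBJ2-1
TCRBJ02-02	TRBJ2-2
TCRBJ02-03	TRBJ2-3
TCRBJ02-04	TRBJ2-4
TCRBJ02-05	TRBJ2-5
TCRBJ02-06	TRBJ2-6
TCRBJ02-07	TRBJ2-7
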