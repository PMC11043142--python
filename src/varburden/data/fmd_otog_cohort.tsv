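contig	pos	ref	alt	rsid	consequence	cds_pos	AF_NFE	AC_NFE	AN_NFE	AF_AFR	AC_AFR	AN_AFR	AF_EAS	AC_EAS	AN_EAS	AF_SAS	AC_SAS	AN_SAS	AF_AMR	AC_AMR	AN_AMR	AF_GLOBAL	AC_GLOBAL	AN_GLOBAL	cohort_ac	cohort_an
NC_000011.10	17553211	G	A	rs552304627	missense	422	1.34e-03	.	.	1.48e-04	.	.	0	.	.	8.88e-05	.	.	1.87e-03	.	.	8.80e-04	.	.	1	200
NC_000011.10	17557227	G	A	rs61978648	missense	806	4.43e-03	.	.	6.28e-02	.	.	0	.	.	1.42e-03	.	.	1.37e-02	.	.	8.36e-03	.	.	5	200
NC_000011.10	17599671	C	T	rs117005078	missense	3719	5.55e-03	.	.	8.81e-04	.	.	0	.	.	7.10e-04	.	.	1.42e-03	.	.	2.73e-03	.	.	1	200
NC_000011.10	17606001	G	A	rs145689709	missense	4058	4.08e-03	.	.	4.43e-04	.	.	0	.	.	4.88e-04	.	.	2.20e-03	.	.	2.42e-03	.	.	1	200
NC_000011.10	17610645	T	C	rs61744602	missense	5381	3.59e-03	.	.	1.47e-04	.	.	0	.	.	0	.	.	1.02e-03	.	.	1.63e-03	.	.	1	200
NC_000011.10	17611118	C	T	rs748280789	missense	5855	3.75e-05	.	.	0	.	.	0	.	.	0	.	.	0	.	.	1.36e-05	.	.	1	200
NC_000011.10	17611374	C	T	rs61736002	missense	6110	1.24e-03	.	.	4.45e-03	.	.	9.34e-05	.	.	4.74e-03	.	.	4.88e-03	.	.	2.47e-03	.	.	5	200
NC_000011.10	17612217	G	A	rs188527711	missense	6215	1.60e-03	.	.	1.47e-04	.	.	3.71e-04	.	.	2.22e-04	.	.	6.92e-04	.	.	7.98e-04	.	.	1	200
NC_000011.10	17635125	G	A	rs76461792	missense	7667	4.89e-03	.	.	1.56e-04	.	.	0	.	.	3.21e-03	.	.	1.64e-03	.	.	2.76e-03	.	.	1	200
NC_000011.10	17638480	C	A	rs61995750	missense	7862	2.01e-04	.	.	1.56e-02	.	.	0	.	.	0	.	.	9.78e-04	.	.	9.84e-04	.	.	1	200
NC_000011.10	17640936	C	T	rs567966154	missense	8072	2.40e-04	.	.	1.27e-02	.	.	9.28e-05	.	.	8.89e-05	.	.	9.37e-04	.	.	8.95e-04	.	.	1	200
NC_000011.10	17641065	G	A	rs1310923563	missense	8201	0	.	.	0	.	.	9.30e-05	.	.	4.44e-05	.	.	0	.	.	1.39e-05	.	.	1	200
NC_000011.10	17642200	G	A	rs117315845	missense	8405	2.89e-03	.	.	0	.	.	9.28e-05	.	.	2.62e-03	.	.	2.57e-03	.	.	2.61e-03	.	.	2	200
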