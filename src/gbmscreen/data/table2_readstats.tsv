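sample_id	library_id	uniquely_mapped	total_reads
NB-00369/13	GB_1	6.57	38.16
17-H-21518	GB_2	6.56	32.52
NB-00464/12	GB_3	11.09	36.74
NB-00079/14	GB_4	5.85	28.14
17-H-05191	GB_5	7.18	38.79
16-H-17976	GB_6	6.19	34.93
NB-00173/14	GB_7	5.80	38.31
NB-00131/12	GB_8	10.55	38.99
NB-00450/12	GB_10	8.36	28.62
NB-00450/12	GB_11	5.84	26.36
NB-00233/12	GB_12	6.97	30.42
NB-00003/15	GB_16	5.53	28.93
17-H-31914	GB_17	7.10	28.03
NB-00094/13	GB_18	8.52	28.62
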