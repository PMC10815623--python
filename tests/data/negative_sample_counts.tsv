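year	quarter	lab	kit	n_negatives
2019	S4	LAB_f	powerplex21	17
2020	S1	LAB_a	agcu_ex22	4
2020	S1	LAB_c	verifiler_plus	32
2020	S1	LAB_e	powerplex21	11
2020	S1	LAB_f	powerplex21	6
2020	S2	LAB_a	agcu_ex22	25
2020	S2	LAB_c	powerplex21	50
2020	S2	LAB_d	powerplex21	8
2020	S2	LAB_e	powerplex21	8
2020	S2	LAB_e	verifiler_plus	5
2020	S2	LAB_f	powerplex21	4
2020	S3	LAB_a	agcu_ex22	23
2020	S3	LAB_c	powerplex21	35
2020	S3	LAB_d	powerplex21	6
2020	S3	LAB_e	powerplex21	13
2020	S3	LAB_f	powerplex21	7
2020	S4	LAB_a	agcu_ex22	26
2020	S4	LAB_c	powerplex21	39
2020	S4	LAB_d	powerplex21	10
2020	S4	LAB_e	powerplex21	11
2020	S4	LAB_f	powerplex21	5
2021	S1	LAB_a	agcu_ex22	29
2021	S1	LAB_c	powerplex21	34
2021	S1	LAB_d	powerplex21	17
2021	S1	LAB_e	powerplex21	10
2021	S1	LAB_f	powerplex21	5
2021	S2	LAB_a	agcu_ex22	23
2021	S2	LAB_c	powerplex21	23
2021	S2	LAB_d	powerplex21	7
2021	S2	LAB_e	powerplex21	12
2021	S2	LAB_f	powerplex21	6
2021	S3	LAB_a	agcu_ex22	26
2021	S3	LAB_b	verifiler_plus	7
2021	S3	LAB_c	verifiler_plus	31
2021	S3	LAB_d	powerplex21	12
2021	S3	LAB_e	verifiler_plus	7
2021	S3	LAB_f	powerplex21	6
2021	S4	LAB_a	agcu_ex22	21
2021	S4	LAB_b	verifiler_plus	12
2021	S4	LAB_c	verifiler_plus	17
2021	S4	LAB_d	powerplex21	16
2021	S4	LAB_e	verifiler_plus	9
2021	S4	LAB_f	powerplex21	4
2022	S1	LAB_a	agcu_ex22	26
2022	S1	LAB_b	verifiler_plus	10
2022	S1	LAB_c	verifiler_plus	56
2022	S1	LAB_e	verifiler_plus	14
2022	S1	LAB_f	powerplex21	8
2022	S2	LAB_a	agcu_ex22	21
2022	S2	LAB_b	verifiler_plus	17
2022	S2	LAB_d	powerplex21	25
2022	S2	LAB_e	verifiler_plus	12
2022	S3	LAB_a	agcu_ex22	20
2022	S3	LAB_d	powerplex21	8
2022	S4	LAB_a	agcu_ex22	25
2022	S4	LAB_d	powerplex21	8
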