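priority	n_proteins	n_significant	max_abs_fold_change	median_cv_replicate	median_cv_rep_sample
1	204	13	1.52	11.97	19.16
2	273	7	4.30	36.60	47.06
overall	477	20	4.30	24.29	33.11
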