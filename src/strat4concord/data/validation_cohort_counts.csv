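analysis_id,analyte,rule_id,stratum,a,b,c,d
esr1_er_1pct,ESR1,er_1pct,,407,4,7,75
esr1_er_10pct,ESR1,er_10pct,,404,7,4,78
pgr_pr_1pct,PGR,pr_1pct,,333,23,23,99
pgr_pr_10pct,PGR,pr_10pct,,320,36,7,115
erbb2_ihc_plus_fish,ERBB2,her2_ihc_plus_fish,,66,29,4,391
erbb2_ihc_excluding_2plus,ERBB2,her2_ihc_excluding_2plus,,42,16,2,361
erbb2_fish_only,ERBB2,her2_fish_only,,56,23,6,242
erbb2_ihc_plus_fish_er_pos,ERBB2,her2_ihc_plus_fish,ER_POSITIVE,39,28,1,341
erbb2_ihc_plus_fish_er_neg,ERBB2,her2_ihc_plus_fish,ER_NEGATIVE,27,1,3,48
mki67_ki67_20pct,MKI67,ki67_20pct,,117,63,15,94
mki67_ki67_10pct,MKI67,ki67_10pct,,155,25,37,72
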