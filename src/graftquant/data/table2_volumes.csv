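patient_id,treated_side,side,timepoint,volume_mm3
8096,Dx,Dx,baseline,159
8096,Dx,Sin,baseline,175
8096,Dx,Dx,6mo,186
8096,Dx,Sin,6mo,0
6754,Sin,Dx,baseline,206
6754,Sin,Sin,baseline,243
6754,Sin,Dx,6mo,165
6754,Sin,Sin,6mo,436
8837,Sin,Dx,baseline,198
8837,Sin,Sin,baseline,384
8837,Sin,Dx,6mo,61
8837,Sin,Sin,6mo,353
8606,Dx,Dx,baseline,552
8606,Dx,Sin,baseline,428
9304,Dx,Dx,baseline,245
9304,Dx,Sin,baseline,233
9304,Dx,Dx,6mo,292
9304,Dx,Sin,6mo,41
1674,Sin,Dx,baseline,682
1674,Sin,Sin,baseline,609
1674,Sin,Dx,6mo,653
1674,Sin,Sin,6mo,826
4252,Dx,Dx,baseline,532
4252,Dx,Sin,baseline,448
4252,Dx,Dx,6mo,585
4252,Dx,Sin,6mo,380
8323,Sin,Dx,baseline,190
8323,Sin,Sin,baseline,248
8323,Sin,Dx,6mo,65
8323,Sin,Sin,6mo,419
5421,Dx,Dx,baseline,318
5421,Dx,Sin,baseline,387
5421,Dx,Dx,6mo,486
5421,Dx,Sin,6mo,86
6922,Dx,Dx,baseline,298
6922,Dx,Sin,baseline,264
6922,Dx,Dx,6mo,430
6922,Dx,Sin,6mo,21
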