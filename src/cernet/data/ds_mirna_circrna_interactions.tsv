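miRNA	circRNA
hsa-miR-155-5p	hsa_circ_0067470
hsa-miR-155-5p	hsa_circ_0035485
hsa-miR-155-5p	hsa_circ_0035488
hsa-miR-155-5p	hsa_circ_0023610
hsa-miR-155-5p	hsa_circ_0035487
hsa-miR-155-5p	hsa_circ_0073445
hsa-miR-155-5p	hsa_circ_0118623
hsa-miR-155-5p	hsa_circ_0067469
hsa-miR-155-5p	hsa_circ_0073443
hsa-miR-155-5p	hsa_circ_0054554
hsa-miR-155-5p	hsa_circ_0120335
hsa-miR-155-5p	hsa_circ_0067472
hsa-miR-155-5p	hsa_circ_0118117
hsa-miR-155-5p	hsa_circ_0138451
hsa-miR-155-5p	hsa_circ_0122061
hsa-miR-155-5p	hsa_circ_0070210
hsa-miR-155-5p	hsa_circ_0024319
hsa-miR-155-5p	hsa_circ_0100932
hsa-miR-155-5p	hsa_circ_0118118
hsa-miR-155-5p	hsa_circ_0100931
hsa-miR-138-5p	hsa_circ_0136728
hsa-miR-138-5p	hsa_circ_0078328
hsa-miR-138-5p	hsa_circ_0035653
hsa-miR-138-5p	hsa_circ_0131090
hsa-miR-138-5p	hsa-circRNA7492-17
hsa-miR-138-5p	hsa-circRNA8910-13
hsa-miR-138-5p	hsa_circ_0091053
hsa-miR-138-5p	hsa_circ_0115879
hsa-miR-138-5p	hsa_circ_0140138
hsa-miR-138-5p	hsa_circ_0022404
hsa-miR-138-5p	hsa_circ_0035649
hsa-miR-138-5p	hsa_circ_0040304
hsa-miR-138-5p	hsa_circ_0104117
hsa-miR-138-5p	hsa_circ_0002138
hsa-miR-138-5p	hsa_circ_0074859
hsa-miR-138-5p	hsa_circ_0109005
hsa-miR-138-5p	hsa_circ_0110582
hsa-miR-138-5p	hsa_circ_0138111
hsa-miR-138-5p	hsa_circ_0055868
hsa-miR-138-5p	hsa_circ_0031781
hsa-miR-146a-5p	hsa-circRNA12419-2
hsa-miR-146a-5p	hsa_circ_0020955
hsa-miR-146a-5p	hsa_circ_0133379
hsa-miR-146a-5p	hsa-circRNA14521
hsa-miR-146a-5p	hsa_circ_0022092
hsa-miR-146a-5p	hsa_circ_0104843
hsa-miR-146a-5p	hsa-circRNA1203-20
hsa-miR-146a-5p	hsa_circ_0020956
hsa-miR-146a-5p	hsa_circ_0128323
hsa-miR-146a-5p	hsa_circ_0052850
hsa-miR-146a-5p	hsa_circ_0015762
hsa-miR-146a-5p	hsa_circ_0129907
hsa-miR-146a-5p	hsa-circRNA2719-14
hsa-miR-146a-5p	hsa_circ_0005383
hsa-miR-146a-5p	hsa_circ_0039257
hsa-miR-146a-5p	hsa_circ_0085586
hsa-miR-146a-5p	hsa_circ_0015760
hsa-miR-146a-5p	hsa_circ_0085389
hsa-miR-146a-5p	hsa_circ_0005365
hsa-miR-146a-5p	hsa_circ_0071467
hsa-miR-802	hsa_circ_0056745
hsa-miR-802	hsa-circRNA12735-2
hsa-miR-802	hsa-circRNA1203-7
hsa-miR-802	hsa_circ_0127798
hsa-miR-802	hsa-circRNA1203-24
hsa-miR-802	hsa-circRNA5535-9
hsa-miR-802	hsa_circ_0027885
hsa-miR-802	hsa-circRNA6265-4
hsa-miR-802	hsa_circ_0005439
hsa-miR-802	hsa_circ_0065029
hsa-miR-802	hsa-circRNA6411-18
hsa-miR-802	hsa_circ_0006084
hsa-miR-802	hsa_circ_0065031
hsa-miR-802	hsa_circ_0095820
hsa-miR-802	hsa-circRNA3109-14
hsa-miR-802	hsa_circ_0097862
hsa-miR-802	hsa_circ_0024603
hsa-miR-802	hsa-circRNA5535-11
hsa-miR-802	hsa_circ_0065030
hsa-miR-802	hsa-circRNA13641-17
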