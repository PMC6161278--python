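# {"oocyte_id": "oocyte_000", "injection": "cRNA", "cnmp": "8Br-cAMP", "bath_label": "NaK_1_1", "temperature_K": 293.15}
time_s,step_index,command_mV,current_uA
0,0,0,0.304090043
0.01,0,0,0.321976859
0.02,0,0,0.323860753
0.03,0,0,0.294927802
0.04,0,0,0.301399691
0.05,0,0,0.315683503
0.06,0,0,0.311226562
0.07,0,0,0.314205135
0.08,0,0,0.305827133
0.09,0,0,0.323136239
0.1,0,0,0.322105123
0.11,0,0,0.314972708
0.12,0,0,0.325570259
0.13,0,0,0.318958632
0.14,0,0,0.305676545
0.15,0,0,0.317943145
0.16,0,0,0.304653212
0.17,0,0,0.323013169
0.18,0,0,0.313716261
0.19,0,0,0.312353971
0.2,0,0,0.307380591
0.21,0,0,0.326402805
0.22,0,0,0.312619812
0.23,0,0,0.30986975
0.24,0,0,0.310619818
0,1,-60,-1.24079484
0.01,1,-60,-1.24254184
0.02,1,-60,-1.24214598
0.03,1,-60,-1.24204084
0.04,1,-60,-1.22500704
0.05,1,-60,-1.25056087
0.06,1,-60,-1.25169113
0.07,1,-60,-1.25477721
0.08,1,-60,-1.24054927
0.09,1,-60,-1.23548776
0.1,1,-60,-1.24798422
0.11,1,-60,-1.25531244
0.12,1,-60,-1.25522071
0.13,1,-60,-1.2405339
0.14,1,-60,-1.23967014
0.15,1,-60,-1.24173294
0.16,1,-60,-1.25388034
0.17,1,-60,-1.24496337
0.18,1,-60,-1.24617686
0.19,1,-60,-1.24521458
0.2,1,-60,-1.23874396
0.21,1,-60,-1.24527811
0.22,1,-60,-1.24077982
0.23,1,-60,-1.24694712
0.24,1,-60,-1.24478478
0,2,-120,-2.64824624
0.01,2,-120,-2.66962421
0.02,2,-120,-2.65873459
0.03,2,-120,-2.66071867
0.04,2,-120,-2.66287278
0.05,2,-120,-2.65969659
0.06,2,-120,-2.64244918
0.07,2,-120,-2.6665027
0.08,2,-120,-2.64859991
0.09,2,-120,-2.67554233
0.1,2,-120,-2.66248618
0.11,2,-120,-2.65792638
0.12,2,-120,-2.65410127
0.13,2,-120,-2.65325392
0.14,2,-120,-2.65282863
0.15,2,-120,-2.66463863
0.16,2,-120,-2.66615762
0.17,2,-120,-2.65333064
0.18,2,-120,-2.66419342
0.19,2,-120,-2.67540099
0.2,2,-120,-2.67433464
0.21,2,-120,-2.67254793
0.22,2,-120,-2.65872752
0.23,2,-120,-2.66261478
0.24,2,-120,-2.65746838
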