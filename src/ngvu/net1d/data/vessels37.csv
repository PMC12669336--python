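id,name,parent_ids,child_ids,L_cm,R0_cm,h0_cm,E_Pa,outlet_flag,source
1,ascending_aorta,,2;3,4.0,1.2,0.163,0.4e6,0,literature
2,aortic_arch_I,1,4;5,2.0,1.12,0.126,0.4e6,0,literature
3,brachiocephalic,1,6;7,3.4,0.62,0.080,0.4e6,0,literature
4,aortic_arch_II,2,8;9,3.9,1.07,0.115,0.4e6,0,literature
5,l_common_carotid,2,10;11,20.8,0.25,0.063,0.4e6,0,literature
6,r_common_carotid,3,12;13,17.7,0.25,0.063,0.4e6,0,literature
7,r_subclavian,3,14;15,3.4,0.423,0.067,0.4e6,0,literature
8,thoracic_aorta,4,,15.6,0.999,0.110,0.4e6,1,literature
9,l_subclavian,4,16;17,3.4,0.423,0.067,0.4e6,0,literature
10,l_external_carotid,5,,17.7,0.15,0.038,0.8e6,1,literature
11,l_internal_carotid_I,5,18;27,17.7,0.2,0.05,0.8e6,0,literature
12,r_internal_carotid_I,6,19;28,17.7,0.2,0.05,0.8e6,0,literature
13,r_external_carotid,6,,17.7,0.15,0.038,0.8e6,1,literature
14,r_vertebral_proximal,7,34;35,9.866,0.136,0.034,0.8e6,0,paper
15,r_brachial,7,,42.2,0.403,0.067,0.4e6,1,literature
16,l_brachial,9,,42.2,0.403,0.067,0.4e6,1,literature
17,l_vertebral_proximal,9,36;37,9.866,0.136,0.034,0.8e6,0,paper
18,l_internal_carotid_II,11,21;23,0.5,0.2,0.05,1.6e6,0,literature
19,r_internal_carotid_II,12,22;24,0.5,0.2,0.05,1.6e6,0,literature
20,basilar,34;36,25;26,2.9,0.162,0.04,1.6e6,0,literature
21,l_middle_cerebral,18,,11.9,0.143,0.036,1.6e6,1,literature
22,r_middle_cerebral,19,,11.9,0.143,0.036,1.6e6,1,literature
23,l_anterior_cerebral_A1,18,29;31,1.2,0.117,0.03,1.6e6,0,literature
24,r_anterior_cerebral_A1,19,30,1.2,0.117,0.03,1.6e6,0,literature
25,l_posterior_cerebral_P1,20,32,0.5,0.107,0.027,1.6e6,0,literature
26,r_posterior_cerebral_P1,20,33,0.5,0.107,0.027,1.6e6,0,literature
27,l_posterior_communicating,11,32,1.5,0.073,0.018,1.6e6,0,literature
28,r_posterior_communicating,12,33,1.5,0.073,0.018,1.6e6,0,literature
29,l_anterior_cerebral_A2,23,,10.3,0.12,0.03,1.6e6,1,literature
30,r_anterior_cerebral_A2,24;31,,10.3,0.12,0.03,1.6e6,1,literature
31,anterior_communicating,23,30,0.3,0.074,0.019,1.6e6,0,literature
32,l_posterior_cerebral_P2,25;27,,8.6,0.105,0.026,1.6e6,1,literature
33,r_posterior_cerebral_P2,26;28,,8.6,0.105,0.026,1.6e6,1,literature
34,r_vertebral_distal,14,20,4.930,0.136,0.034,0.8e6,0,paper
35,r_pica_branch,14,,6.000,0.080,0.034,0.8e6,1,paper
36,l_vertebral_distal,17,20,4.930,0.136,0.034,0.8e6,0,paper
37,l_pica_branch,17,,6.000,0.080,0.034,0.8e6,1,paper
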