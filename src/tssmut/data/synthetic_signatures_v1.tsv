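channel	SYN1	SYN2	SYN3	SYN4	SYN5
A[C>A]A	1.71e-06	0.01147931	6.244e-05	0.0008875	0.0097591
A[C>A]C	0.00183544	0.01822505	0.03698114	0.01666323	0.00356667
A[C>A]G	0.00312768	0.00435173	0.00642235	0.00050582	0.00041714
A[C>A]T	0.00261184	0.00073986	0.01013884	0.00063346	0.00144118
A[C>G]A	0.02624532	0.01193419	0.01788053	0.00192725	0.01645127
A[C>G]C	0.00174389	0.00026843	0.02336052	3.267e-05	2e-08
A[C>G]G	0.0187193	0.00144499	0.00425518	0.0014291	0.01992043
A[C>G]T	0.01031096	0.00493804	0.0003987	2.367e-05	0.00239054
A[C>T]A	0.00014799	0.00519793	0.00183356	4.13e-06	0.00092617
A[C>T]C	0.01377872	2e-08	1.87e-06	0.00014912	0.00618918
A[C>T]G	0.00010906	0.0046599	0.02111616	0.01698357	0.01970714
A[C>T]T	0.0010335	0.02935214	0.00321429	0.03902103	7.58e-06
A[T>A]A	0.0068538	0.08989928	0.01566855	0.00868709	2.96e-06
A[T>A]C	0.00130959	0.04960548	0.00549018	0.04422467	0.02095424
A[T>A]G	0.00513872	0.00163457	0.05463487	0.00360521	0.00403682
A[T>A]T	1.18e-06	0.00153141	0.00137503	0.00443251	2e-08
A[T>C]A	0.00073994	6.179e-05	0.00777869	0.0016426	0.00302763
A[T>C]C	0.00082951	0.00263708	0.04311194	0.00293288	0.02307488
A[T>C]G	0.02394721	0.01885892	0.06378124	0.00311407	0.00051011
A[T>C]T	0.0130186	0.01149624	0.01903796	0.00553562	0.02529575
A[T>G]A	0.00486168	0.01211504	0.05192654	0.00020777	0.01357372
A[T>G]C	0.02420513	0.0025765	9.682e-05	0.00020169	0.00037503
A[T>G]G	0.00913978	0.01553178	0.03318923	0.00045235	0.0159181
A[T>G]T	0.00015803	0.01704964	0.01085762	0.02515393	0.00180773
C[C>A]A	5.137e-05	0.04327139	0.03004455	0.05096939	0.00163504
C[C>A]C	6.89e-06	0.00793994	0.00025932	0.00125409	0.00095723
C[C>A]G	0.01072708	0.02794472	0.00043821	0.00917239	0.00331579
C[C>A]T	0.00132913	0.030768	0.00435859	0.0452245	9.234e-05
C[C>G]A	0.00175148	0.00016979	0.03492721	0.00156733	0.00141859
C[C>G]C	3.91e-06	0.00297832	0.02956561	0.03391192	0.01505653
C[C>G]G	0.00065848	0.00820856	0.0086905	2e-08	0.0001335
C[C>G]T	0.00560317	3.253e-05	0.00023381	0.03211371	0.00286964
C[C>T]A	0.00012226	0.01031985	0.00039054	0.00666604	0.1003858
C[C>T]C	0.0233594	0.01321389	0.01805136	0.00660815	0.04385269
C[C>T]G	0.0038544	2.11e-06	0.00037781	0.00327526	0.0012177
C[C>T]T	8.005e-05	7.288e-05	2.472e-05	0.0064826	0.00094452
C[T>A]A	0.00937806	0.01028402	0.00037822	0.01183301	0.00163031
C[T>A]C	7.72e-06	0.00011192	2.289e-05	0.00974273	0.00312838
C[T>A]G	0.06852937	0.00053883	0.02236178	4.22e-06	0.00760064
C[T>A]T	0.00079595	0.00038911	1.9e-05	0.05914262	0.0007155
C[T>C]A	0.00636904	0.00532633	0.01747834	0.02454192	0.0
C[T>C]C	0.00864812	0.01869227	0.01650565	0.07622599	1.516e-05
C[T>C]G	0.00023512	1.397e-05	0.00351005	0.0	0.00349321
C[T>C]T	0.01117189	0.00184402	0.00068779	0.00449579	4.073e-05
C[T>G]A	0.00343881	0.00144388	5.6e-06	0.0067987	5.7e-07
C[T>G]C	0.00028785	1.09e-06	0.00070298	0.01509944	0.00010277
C[T>G]G	0.00883691	5.621e-05	1.4e-07	0.01046095	0.00942036
C[T>G]T	0.04964765	8.515e-05	0.00028693	0.00077217	0.00134455
G[C>A]A	0.00497575	0.00477052	4.101e-05	0.00230236	1.805e-05
G[C>A]C	0.07443287	0.00367887	0.01323748	0.02124138	0.0449517
G[C>A]G	0.00163098	7.303e-05	0.00015379	0.01770702	0.00042949
G[C>A]T	4.1e-07	0.00932132	0.0187797	0.00014056	0.00309128
G[C>G]A	0.00056449	0.02542541	0.00115463	0.03482238	0.03854737
G[C>G]C	0.00406767	0.00518896	0.00378271	0.00138413	0.00530054
G[C>G]G	4.98e-06	0.0008949	0.05053078	0.03142811	4e-08
G[C>G]T	0.00673822	0.00063544	0.00469733	0.01075103	0.03047317
G[C>T]A	0.00010877	2.27e-06	0.00018392	0.00257411	0.02099582
G[C>T]C	0.0001734	0.00794539	0.00020267	3.5e-05	0.01046405
G[C>T]G	0.0014432	0.01673354	7.767e-05	0.00135992	7.2e-07
G[C>T]T	0.00341718	0.00254472	0.00772194	0.00397296	5.28e-06
G[T>A]A	7.34e-06	4.73e-06	0.02315869	0.00622661	0.00949781
G[T>A]C	7.579e-05	0.03347285	6e-08	1.208e-05	0.01745473
G[T>A]G	1e-08	0.05456186	0.00148896	0.01846084	0.00218727
G[T>A]T	0.04094165	0.00100186	1.01e-06	0.00016899	0.00198742
G[T>C]A	8e-08	0.00295824	0.00412512	0.00126466	0.00791346
G[T>C]C	0.00026623	0.00139238	0.01695584	0.00565632	0.00926189
G[T>C]G	0.03813748	0.09948985	0.0019149	0.03155004	0.05294154
G[T>C]T	4.65e-06	0.01243137	0.00070335	8.011e-05	0.00205448
G[T>G]A	0.15764475	0.0272068	2.3e-07	0.0002078	0.00087056
G[T>G]C	9e-08	0.00065006	0.00050095	0.00951708	0.06929318
G[T>G]G	0.0113531	0.00897904	0.00016546	2.1e-07	0.00036013
G[T>G]T	0.01167089	6.803e-05	0.00411028	0.0027644	0.01927687
T[C>A]A	2.842e-05	3.13e-06	0.00313647	0.0	0.00218047
T[C>A]C	0.00595721	8.43e-06	2e-08	5.707e-05	0.00060301
T[C>A]G	0.00253432	0.01500923	0.00757062	0.00449482	0.01087066
T[C>A]T	0.00545894	0.05025005	0.00279349	0.00198481	0.00922548
T[C>G]A	7.76e-06	6.95e-06	0.01783105	0.05949752	0.00523439
T[C>G]C	0.00059844	0.03391123	0.00821054	0.00823064	0.00019451
T[C>G]G	0.04164537	1.588e-05	0.0048183	0.00051443	0.0294613
T[C>G]T	3.3e-07	9.924e-05	0.01771975	0.00674957	0.00230496
T[C>T]A	1.61e-06	0.00628738	0.03222405	1.036e-05	0.00037659
T[C>T]C	0.0034875	8.818e-05	1.1e-07	0.00515322	0.01199065
T[C>T]G	0.00667812	0.0030821	0.02366815	0.00051088	0.00328517
T[C>T]T	9.971e-05	0.01520882	0.00269066	0.01031911	0.01744005
T[T>A]A	7.559e-05	2.41e-05	4.537e-05	0.01565024	0.02204978
T[T>A]C	0.01647983	0.000361	3.8e-06	0.00560747	2.885e-05
T[T>A]G	0.00217335	0.00029076	1e-08	2.683e-05	0.01004312
T[T>A]T	1.198e-05	0.00045158	0.02481787	0.00217274	0.00359483
T[T>C]A	8.55e-06	0.04001714	0.000741	0.02038765	0.00213296
T[T>C]C	0.01244417	1.028e-05	0.0001476	0.00344743	0.00060493
T[T>C]G	0.01512893	0.00123954	2.874e-05	0.00027005	0.08292543
T[T>C]T	0.00020107	1.554e-05	0.02938887	0.00599709	2.72e-06
T[T>G]A	0.13007457	1.807e-05	4.96e-06	0.01843589	0.00962978
T[T>G]C	0.00290513	0.0049749	0.00123497	0.00021046	0.01308238
T[T>G]G	0.00362575	0.00013719	9.509e-05	0.03036339	3.41e-06
T[T>G]T	0.00795068	0.0097597	0.04720421	0.00146634	0.02663276
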