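eve	similar_virus	similar_protein	eve_len_aa	ref_len_aa
Cyphomyrmex costatus EVE18	Wuchang cockroach virus 3	Glycoprotein	586	659
Linepithema humile EVE6	Hubei narna-like virus 19	RdRP	750	737
Monomorium pharaonis EVE2	Densovirus SC1065	VP1	215	288
Pogonomyrmex barbatus EVE34	Wuhan mosquito virus 8	Glycoprotein	582	653
Pseudomyrmex gracilis EVE3	Cyclovirus PK5034	Rep-associated	236	277
Pseudomyrmex gracilis EVE4	Densovirus SC1065	VP1	281	288
Pseudomyrmex gracilis EVE41	Wuchang cockroach virus 3	Glycoprotein	641	659
Pseudomyrmex gracilis EVE45	Wuhan insect virus 16	Nucleoprotein	294	327
Pseudomyrmex gracilis EVE48	Wuhan mosquito virus 8	Glycoprotein	624	653
Solenopsis invicta EVE17	Wuhan mosquito virus 8	Glycoprotein	582	653
Trachymyrmex cornetzi EVE19	Wuchang cockroach virus 3	Glycoprotein	605	659
Trachymyrmex septentrionalis EVE19	Wuhan mosquito virus 8	Glycoprotein	612	653
Vollenhovia emeryi EVE10	Hubei partiti-like virus 11	Capsid	412	475
Vollenhovia emeryi EVE17	Wuhan insect virus 16	Nucleoprotein	327	327
Vollenhovia emeryi EVE19	Wuhan insect virus 16	Nucleoprotein	326	327
Wasmannia auropunctata EVE12	Wuhan mosquito virus 8	Glycoprotein	595	653
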