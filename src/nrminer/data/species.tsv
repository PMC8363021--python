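# The 33 flatworm species of the survey, with class/order/family taxonomy
# and the lineage key used for class-level gain/loss analysis.
code	species	taxon_class	order	family	lineage
Ml	Macrostomum lignano	Rhabditophora	Macrostomida	Macrostomidae	Ml
Sme	Schmidtea mediterranea	Rhabditophora	Tricladida	Dugesidae	Sme
Gs	Gyrodactylus salaris	Monogenea	Monopisthocotylea	Gyrodactylidae	Monogenea
Px	Protopolystoma xenopodis	Monogenea	Polyopisthocotylea	Polystomatidae	Monogenea
Hd	Hymenolepis diminuta	Cestoda	Cyclophyllidea	Hymenolepididae	Cestoda
Hm	Hymenolepis microstoma	Cestoda	Cyclophyllidea	Hymenolepididae	Cestoda
Hn	Hymenolepis nana	Cestoda	Cyclophyllidea	Hymenolepididae	Cestoda
Ec	Echinococcus canadensis	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Eg	Echinococcus granulosus	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Em	Echinococcus multilocularis	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Ta	Taenia asiatica	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Tm	Taenia multiceps	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Ts	Taenia saginata	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Tso	Taenia solium	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Ht	Hydatigera taeniaeformis	Cestoda	Cyclophyllidea	Taeniidae	Cestoda
Mc	Mesocestoides corti	Cestoda	Cyclophyllidea	Mesocestoididae	Cestoda
Dl	Diphyllobothrium latum	Cestoda	Diphyllobothriidea	Diphyllobothriidae	Cestoda
Ss	Schistocephalus solidus	Cestoda	Diphyllobothriidea	Diphyllobothriidae	Cestoda
Se	Spirometra erinaceieuropaei	Cestoda	Diphyllobothriidea	Diphyllobothriidae	Cestoda
Cs	Clonorchis sinensis	Trematoda	Opistorchida	Opistorchiidae	Trematoda
Of	Opisthorchis felineus	Trematoda	Opistorchida	Opistorchiidae	Trematoda
Ov	Opisthorchis viverrini	Trematoda	Opistorchida	Opistorchiidae	Trematoda
Eca	Echinostoma caproni	Trematoda	Echinostomida	Echinostomatidae	Trematoda
Fh	Fasciola hepatica	Trematoda	Echinostomida	Fasciolidae	Trematoda
Sb	Schistosoma bovis	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sc	Schistosoma curassoni	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sh	Schistosoma haematobium	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sj	Schistosoma japonicum	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sm	Schistosoma mansoni	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sma	Schistosoma margrebowiei	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Smt	Schistosoma mattheei	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Sr	Schistosoma rodhaini	Trematoda	Strigeidida	Schistosomatidae	Trematoda
Tr	Trichobilharzia regenti	Trematoda	Strigeidida	Schistosomatidae	Trematoda
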