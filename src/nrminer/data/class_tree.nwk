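(Outgroup,(Ml,(Sme,(Monogenea,(Cestoda,Trematoda)CestTrem)Parasites)SmePar)Platy)Root;
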