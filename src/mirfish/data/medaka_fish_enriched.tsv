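mirna_type	sequence	species
let-7h	UGAGGUAGUAAGUUGUGUUGUU	dre,fru,tni
let-7j	UGAGGUAGUUGUUUGUACAGUU	dre,fru,tni
miR-10c	UACCCUGUAGAUCCGGAUUUGU	dre,fru,tni
miR-10d	UACCCUGUAGAACCGAAUGUGU	dre,fru,tni,ola
miR-16b	UAGCAGCACGUAAAUAUUGGAG	dre
miR-457a	AAGCAGCACAUCAUUACUGGUA	dre
miR-19d	UGUGCAAACCCAUGCAAAACUG	dre,ola
miR-22b	AAGCUGCCAGUUGAAGAGCUGU	dre,fru,tni
miR-27c	UUCACAGUGGUUAAGUUCUGC	dre,fru,tni,ola
miR-27e	UUCACAGUGGCUAAGUUCAGU	dre,fru,tni
miR-130c	CAGUGCAAUAUUAAAAGGGCAUU	dre,ola
miR-135c	UAUGGCUUUCUAUUCCUAUGUG	dre
miR-301c	CAGUGCAAUAGUAUUGUCAUA	dre
miR-456	CAGGCUGGUUAGAUGGUUGUCU	dre
miR-458	AUAGCUCUUUAAAUGGUACU	dre,fru,tni,ola
miR-460	CCUGCAUUGUACACACUGUGC	dre,fru,tni,ola
miR-462	UAACGGAACCCAUAAUGCAGCUG	dre,ola
miR-722	UUUUGCAGAAACGUUUCAGAUU	dre
miR-723	AGACAUCAGAAAAAUCUGUGCU	dre
miR-724	UUAAAGGGAAUUUGCGACUGUU	dre
miR-725	UUCAGUCAUUGUUUCUGGUCGU	dre
miR-727	UUGAGGCGAGUUGAAGACUUCA	dre
miR-728	AUACUAAGUAUACUACGUUUAC	dre
miR-730	UCCUCAUUGUGCAUGCUGUGUG	dre
miR-731	AAUGACACGUUUUCUCCCGGAUU	dre,ola
miR-734	UAAAUGCUGCAGAAUUGUGC	dre
miR-737	AAAUCAAAGCCUAAAGAAAAUA	dre
miR-1388	AUCUCAGGUUCGUCAGCCCAUG	dre,ola
miR-2184	AACAGUAAGAGUUUAUGUGCUG	dre
miR-2187	UUACAGGCUAUGCUAAUCUGU	dre
miR-2188	AAGGUCCAACCUCACAUGUCCU	dre
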