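>dre-let-7h
UGAGGUAGUAAGUUGUGUUGUU
>dre-let-7j
UGAGGUAGUUGUUUGUACAGUU
>dre-miR-10c
UACCCUGUAGAUCCGGAUUUGU
>dre-miR-10d
UACCCUGUAGAACCGAAUGUGU
>dre-miR-16b
UAGCAGCACGUAAAUAUUGGAG
>dre-miR-457a
AAGCAGCACAUCAUUACUGGUA
>dre-miR-19d
UGUGCAAACCCAUGCAAAACUG
>dre-miR-22b
AAGCUGCCAGUUGAAGAGCUGU
>dre-miR-27c
UUCACAGUGGUUAAGUUCUGC
>dre-miR-27e
UUCACAGUGGCUAAGUUCAGU
>dre-miR-2184
AACAGUAAGAGUUUAUGUGCUG
>dre-miR-2187
UUACAGGCUAUGCUAAUCUGU
>dre-miR-2188
AAGGUCCAACCUCACAUGUCCU
>ola-miR-10d
UACCCUGUAGAACCGAAUGUGU
>ola-miR-27c
UUCACAGUGGUUAAGUUCUGC
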