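>REF_I_1|I
WRKYGQKETFFEKRQCVKEPCTFRIQRDILSKGIINPGVPLEVHEH
>REF_I_2|I
WRKYGQKKPANMAEQCQKMRCDKLTMPNTLMVVEAQVLVANAGSHLH
>REF_IIa_1|IIa
WRKYGQKKFARQEDECSKEAFCESPSNQAGPQQIKFPLNNAQVFHSH
>REF_IIb_1|IIb
WRKYGQKNRKEPRLVCTIIDACIASGFFDSLLLKVMRAEVAPNVVHTH
>REF_IIc_1|IIc
WRKYGQKDARGRADTCQMIACPFKSPIDPRFIFRTRGEGPGSLPHIH
>REF_IId_1|IId
WRKYGQKTEDLREMFCSFRIPCVFFPFLGVFGAMLSSIVVDQTFPHRH
>REF_IIe_1|IIe
WRKYGQKDILTKETICMTPLECFGGPQFTGLVFQNFGSISGNGFLHDH
>REF_III_1|III
WRKYGQKMILSPMTSCSLQRMPMCELDRFEKEEQERKIAESPEPTAPHSC
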