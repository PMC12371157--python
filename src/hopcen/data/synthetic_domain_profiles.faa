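>GAG synthetic stand-in consensus for the capsid (GAG) domain
MGSRQLAELRKQVAELQAQNRGGAPKCFNCGKEGHIARNCPNKQGGWARSSQ
>PRO synthetic stand-in consensus for the aspartic protease (PRO) domain
TVPVKLLFDTGADVSVISKRHAEKLGLKTEPLGAAEVVGVGGQALKPLGRIE
>RT synthetic stand-in consensus for the reverse transcriptase (RT) domain
KLNPAKSPWASPVVLVPKKDGSTRFCVDYRALNKVTIKDRYPLPRIDELFDQ
>RH synthetic stand-in consensus for the RNase H (RH) domain
LTEAHEGLGAVLSQRDEAGHERVIAYASRSLSKAERNYSTTEKECLAVVWAI
>INT synthetic stand-in consensus for the integrase (INT) domain
GPFERLSMDFITGLPKSRGYDAILVVVDRFSKMAHFIPCSKTDDASHVADLF
>CHD synthetic stand-in consensus for the integrase C-terminal chromodomain (CHD)
EYLVKWKGLPESENSWEPAENLQNAPDLVKAYEASRSQGNTRSRVASAKRKR
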