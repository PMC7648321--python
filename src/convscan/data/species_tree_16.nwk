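(STRCA,(GALGA,((PHORU,PODCR),((CALAN,CAPCA),((GAVST,(PHACA,EGRGA)),(((CATAU,(HALAL,HALLE)),(TYTAL,PICPU)),(FALPE,TAEGU)))))));
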