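>GRE curated stand-in for the glucocorticoid response element (GGTACAnnnTGTTCT)
A [  1  1  1 97  1 97 25 25 25  1  1  1  1  1  1 ]
C [  1  1  1  1 97  1 25 25 25  1  1  1  1 97  1 ]
G [ 97 97  1  1  1  1 25 25 25  1 97  1  1  1  1 ]
T [  1  1 97  1  1  1 25 25 25 97  1 97 97  1 97 ]
>AP-1 curated stand-in for the AP-1/TRE element (core TGACTCA with soft flanks)
A [ 13 61  1  1 97  1  1  1 97 13 13 ]
C [ 13 13  1  1  1 97  1  1  1 13 61 ]
G [ 61 13  1 97  1  1  1  1  1 13 13 ]
T [ 13 13 97  1  1  1 97 97  1 61 13 ]
>ETS curated stand-in for an ETS1-family motif (ACAGGAAGTG); the exact family member the core GGAA motif belongs to is unresolved
A [ 97  1 97  1  1 97 97  1  1  1 ]
C [  1 97  1  1  1  1  1  1  1  1 ]
G [  1  1  1 97 97  1  1 97  1 97 ]
T [  1  1  1  1  1  1  1  1 97  1 ]
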