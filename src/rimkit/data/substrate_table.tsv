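name	encoded_suffix	added_tail	observed_rate
RpsF-10Glu	DNADE	EEEEEEEEEE	EQUIVALENT
RpsF-10Asp	DNADE	DDDDDDDDDD	NIL
RpsF-1Glu9Asp	DNADE	EDDDDDDDDD	NIL
RpsF-2Glu8Asp	DNADE	EEDDDDDDDD	NIL
RpsF-3Glu7Asp	DNADE	EEEDDDDDDD	NIL
RpsF-Cmix4	DNADE	EEEDDEEEEE	NIL
RpsF-Extend7	DNADE	EEEEDDDDDD	VERY_SLOW
RpsF-Cmix2	DNADE	EEEEDEEEDE	VERY_SLOW
RpsF-Cmix1	DNADE	EEEEDEEEEE	VERY_SLOW
RpsF-Extend11	DNADE	DDDDEEEEEE	SLOW
RpsF-Cmix3	DNADE	EEEDEEEEEE	SLOW
RpsF-Extend8	DNADE	EEEEEDDDDD	REDUCED
RpsF-Extend9	DNADE	DEEEEEEEEE	REDUCED
RpsF-Cmix6	DNADE	EDEEEEEEEE	REDUCED
RpsF-Cmix5	DNADE	EEDEEEEEEE	REDUCED
RpsF-Extend10	DNADE	DDDEEEEEEE	REDUCED
RpsF-KR-Cmix6	DNAKR	EDEEEEEEEE	SLOW
RpsF-E140K-10Glu	DNADK	EEEEEEEEEE	SLOW
RpsF-D139K-10Glu	DNAKE	EEEEEEEEEE	REDUCED
RpsF-D139A-10Glu	DNAAE	EEEEEEEEEE	REDUCED
RpsF-E140D-10Glu	DNADD	EEEEEEEEEE	REDUCED
EcRpsF-Cmix6	GDSEE	EDEEEEEEEE	REDUCED
RpsI-tail5		DNADEEEEEEEEEEE	REDUCED
RpsI-tail3		NADEEEEEEEEEEE	EQUIVALENT
RpsI-tail2		ADEEEEEEEEEEE	EQUIVALENT
RpsI-tail1		DEEEEEEEEEEE	EQUIVALENT
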