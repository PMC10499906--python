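>Q9LED1 Pru p 3.0102 non-specific lipid transfer protein 1, mature chain (91 aa)
ITCGQVSSALAPCIPYVRGGGAVPPACCNGIRNVNNLARTTPDRQAACNCLKQLSASVPG
VNPNNAAALPGKCGVSIPYKISASTNCATVK
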