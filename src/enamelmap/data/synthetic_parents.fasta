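>AMELX_P190_SYN synthetic stand-in parent embedding the P190 amelogenin marker peptide at a tryptic-producible position; NOT the real porcine sequence
MKLPPHPGHPGYINFSYEKWYQSIAEVTPLHSMKPVQSFLAHK
>AMELX_P173_SYN synthetic stand-in parent embedding the P173/LRAP amelogenin N-terminal marker peptide (phospho-serine at parent position 16); NOT the real porcine sequence
MPLPPHPGHPGYINFSYEVLTPLKWYQSIAEVTPLHSMKPVQSFLAHK
>AMBN_SYN synthetic stand-in parent embedding the ameloblastin N-terminal marker peptide; NOT the real porcine sequence
MKQPGTPGVASLSLETMRAFSMQDLTPAEGAVK
>ENAM_SYN synthetic stand-in parent embedding the enamelin 32 kDa marker peptide; NOT the real porcine sequence
MKGYHGFGGRPPYYSEEMFEQDFEKPKAVDSFAHMGQSLK
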