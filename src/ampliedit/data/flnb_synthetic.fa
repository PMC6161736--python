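>flnb_synthetic synthetic 100-nt Flnb-like amplicon (not mm10 sequence)
TAGAGGCTGGAACCACCAAGACTTATTATTCCTAGCATTCAGGTGAGGCCAACACAGACTAAGGTAATAAAAGACCACTAGTATAACTAAAAGTGTGGTG
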