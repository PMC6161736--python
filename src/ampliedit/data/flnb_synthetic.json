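{
  "name": "flnb_synthetic",
  "comment": "Synthetic amplicon fixture: preserves the genomic geometry of the murine Flnb editing region (Q/R, S/G, intron+4 spacings and the CAG|gtgagg donor 9-mer) on an otherwise artificial sequence.",
  "anchor_chrom": "chr14",
  "anchor_pos": 7936008,
  "strand": "+",
  "primer_fwd": "TAGAGGCTGGAACCACCAAG",
  "primer_rev": "CACCACACTTTTAGTTATAC",
  "sites": [
    {"role": "S/G", "genomic_pos": 7936041, "ref_base": "A", "region": "exonic"},
    {"role": "Q/R", "genomic_pos": 7936048, "ref_base": "A", "region": "exonic"},
    {"role": "intron+4", "genomic_pos": 7936053, "ref_base": "A", "region": "intronic"},
    {"role": "control_1", "offset": 10, "ref_base": "A", "region": "exonic"},
    {"role": "control_2", "offset": 20, "ref_base": "A", "region": "exonic"},
    {"role": "control_3", "offset": 70, "ref_base": "A", "region": "intronic"}
  ]
}
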