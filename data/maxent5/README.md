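# Maximum-entropy donor model tables

`ampliedit.splice.load_splice_model` expects the trained maximum-entropy 5′
splice-site model in the score5ss table dialect in this directory: a file
named `me2x5` with 16384 (4^7) whitespace-separated positive probability
ratios, ordered base-4 (A<C<G<T) over the 7 non-consensus donor positions
(the 9-mer minus the near-invariant GT at intron +1/+2).

These trained tables are distributed with the MaxEntScan software
(`score5.pl` and its `splicemodels/` directory) and are not bundled here.
Copy `splicemodels/me2x5` into this directory to enable maximum-entropy
scoring; without it, the package falls back to `PwmDonorModel`, whose scores
preserve the variant ranking but are not numerically comparable.
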