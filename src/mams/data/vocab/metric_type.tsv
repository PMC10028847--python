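token	description	parent	aliases	provenance
distance	Smaller values denote more relatedness between observations or features (e.g. euclidean distance).			builtin
similarity	Larger values denote more relatedness between observations or features (e.g. Pearson correlation).			builtin
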