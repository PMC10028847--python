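token	description	parent	aliases	provenance
transformation	Values of the parent matrix were transformed (e.g. normalization, log transform, scaling) without subsetting.			builtin
subset	A subset of the parent matrix's observations and/or features.			builtin
concatenation	Observations or features of multiple parent matrices were concatenated.			builtin
reduction	A reduced dimensional representation derived from the parent matrix.			builtin
factorization	A factorization of the parent matrix into component matrices.			builtin
aggregation	Observations or features of the parent matrix or matrices were aggregated (e.g. pseudobulk summation).			builtin
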