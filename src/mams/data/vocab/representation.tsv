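token	description	parent	aliases	provenance
dense	A dense two-dimensional matrix.			provisional
sparse	A sparse matrix storing only non-zero values.			provisional
dataframe	A data frame that may contain mixed data types.		data frame	provisional
vector	A matrix with one dimension.			provisional
tensor	A multidimensional array with more than two dimensions.		multidimensional array	provisional
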