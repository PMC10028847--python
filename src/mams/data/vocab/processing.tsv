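token	description	parent	aliases	provenance
raw	Original measurements that have not been altered.			builtin
counts	Raw data for assays that produce integer-like data such as scRNA-seq. Child of raw.	raw		builtin
intensities	Raw data for assays that produce continuous data such as fluorescent intensities. Child of raw.	raw	intensity	builtin
decontaminated	Measurements have been corrected for background signal (e.g. ambient RNA removal in single-cell RNA-seq).			builtin
lograw	The log of the raw data.	raw		inferred
logcounts	The log of the raw counts.	counts		inferred
logintensities	The log of the raw intensity values.	intensities		inferred
corrected	Measurements have been corrected for observation-level covariates (e.g. batch).			builtin
normalized	Data that has been normalized for differences in overall signal abundance between observations (e.g. correcting for total UMIs or reads per cell).			builtin
lognormalized	Data that has been log transformed after normalizing for differences in overall signal abundance between observations. Child of normalized.	normalized	log normalized	builtin
centered	Data with features that have been made to center around a standard quantity such as the mean or median.			builtin
scaled	Data with features that have been centered around a standard quantity and standardized to have similar variances or ranges (e.g. z-scored).			builtin
reduction	A matrix containing a data dimensionality reduction generally useful for input into tools for downstream analysis such as clustering or 2D-embedding (e.g. PCA, ICA, autoencoders).			builtin
embedding	A matrix containing a low dimensional embedding (usually 2D or 3D) generally used for visualization (e.g. UMAP, tSNE). Child of reduction.	reduction		builtin
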