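token	description	parent	aliases	provenance
full	All original observations are present (e.g. every droplet produced by the device).			builtin
filtered	Observations with enough total signal above background (e.g. droplets containing true cells).			builtin
detected	Observations with minimum levels of detection across features.			builtin
nonartifact	Observations retained after other quality-control filtering (e.g. doublet or high-mitochondrial-fraction removal).		non-artifact	builtin
clean	An analysis-ready set of observations.			builtin
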