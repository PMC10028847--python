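token	description	parent	aliases	provenance
full	All original features are present.			provisional
detected	Features detected above a minimum level across observations.			provisional
variable	Highly variable features selected for downstream analysis.		highly variable	provisional
selected	Features selected by another statistical criterion (e.g. top principal components by variance explained).			provisional
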