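token	description	parent	aliases	provenance
cell	Each observation is an individual cell.			provisional
droplet	Each observation is a microfluidic droplet, which may or may not contain a cell.			provisional
bead	Each observation is a bead.			provisional
spot	Each observation is a spatial capture spot.			provisional
cell_pool	Each observation is a pool of cells (e.g. a pseudobulk aggregate).		cell pool	provisional
subcellular_region	Each observation is a region within a cell.		subcellular region	provisional
roi	Each observation is a region of interest, such as a cell neighborhood or functional tissue unit.		region of interest	provisional
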