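token	description	parent	aliases	provenance
rna	Measurements quantify RNA transcript abundance (e.g. UMI-corrected mRNA counts).			builtin
protein	Measurements quantify protein or epitope abundance (e.g. antibody-derived tag counts).			builtin
chromatin	Measurements quantify chromatin state or accessibility (e.g. ATAC-seq fragment counts in peaks).			builtin
dna	Measurements quantify DNA-level features (e.g. copy number, variant allele frequencies).			builtin
lipid	Measurements quantify lipid abundance.			builtin
metabolite	Measurements quantify metabolite abundance.			builtin
morphology	Measurements quantify morphological features such as size and shape categories.			builtin
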