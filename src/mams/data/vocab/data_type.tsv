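token	description	parent	aliases	provenance
int	Integer-valued data (e.g. UMI counts).		integer	provisional
double	Continuous floating-point data.		float	provisional
boolean	Logical data.		bool	provisional
string	Character data.		character	provisional
mixed	Columns of differing types (e.g. a data frame with continuous and categorical morphological features).			provisional
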