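# Synthetic stand-in restraint table: only the binding Phi values printed in
# the main text are included (the full experimental set is user-replaceable).
# The ACTR helix-1 Ala->Gly site is a placeholder residue id within helix 1.
chain	res_id	phi
N	2098	0.45
N	2073	0.49
A	1049	0.24
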