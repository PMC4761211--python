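>ESLA-7
# Seven HG-U133A probe sets; one per line (gene symbol after a tab is ignored)
202604_x_at	ADAM10
203764_at	DLGAP5
204146_at	RAD51AP1
205588_s_at	FGFR1OP
218663_at	NCAPG
219306_at	KIF15
219918_s_at	ASPM
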