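monocyte8	monocyte-associated BCL-2 inhibitor resistance genes	BCL3	CD14	LILRB1	LRP1	MAFB	PSAP	SLC15A3	SLC7A7
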