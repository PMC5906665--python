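name	formula	synonyms
apigenin	C15H10O5
chrysoeriol	C16H12O6
eriodictyol	C15H12O6
luteolin	C15H10O6
methylluteolin	C16H12O6	diosmetin
naringenin	C15H12O5
quercetin	C15H10O7
resokaempferol	C15H10O5
sakuranetin	C16H14O5
tricetin	C15H10O7
tricin	C17H14O7
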