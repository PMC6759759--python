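gene	category
wzy	LPS
galU	LPS
rmlA	LPS
wapH	LPS
ssg	LPS
pilB	TYPE_IV_PILUS
pilN	TYPE_IV_PILUS
pilR	TYPE_IV_PILUS
pilT	TYPE_IV_PILUS
pilU	TYPE_IV_PILUS
pilY1	TYPE_IV_PILUS
pilE	TYPE_IV_PILUS
ssb	OTHER
PA3263	OTHER
PA0429	UNKNOWN
PA3676	UNKNOWN
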