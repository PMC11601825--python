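unit	context	count	replace_with	remove	invalidate	allow
=	mean age = 30 years	65				x
–	20–67 years	31	-			
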