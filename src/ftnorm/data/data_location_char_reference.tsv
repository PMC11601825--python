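unit	context	count	replace_with	remove	invalidate	allow
&	Abstract & p. 664	53	and			
€	[Fig F1] and [Fig F1]â€”figure supplement 1 and PDB 6HD8	10			x	
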