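name	pattern	valid	standard_form
bracketed reference	[bracketed_ref(0)]	true	[0]
url	[url(0)]	true	[0]
pdb id	[pdb(0)][pdb_id(1)]	true	[0] [1]
loc number	[location(0)][number(1)]	true	[0] [1]
modified location number	[modifier(0)][location(1)][number(2)]	true	[0] [1] [2]
location only	[location(0)]	true	[0]
bare number	[number(0)]	false	
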