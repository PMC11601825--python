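name	pattern	valid	standard_form
number unit	[number(0)][unit(1)]	true	[0] [1]
hyphenated range	[number(0)][number(1)][unit(2)]	true	[0]-[1] [2]
range	[number(0)][range_indicator(1)][number(2)][unit(3)]	true	[0]-[2] [3]
statistical	[statistical(0)][number(1)][unit(2)]	true	[0]: [1] [2]
statistical trailing	[number(0)][unit(1)][statistical(2)]	true	[2]: [0] [1]
numerical exact value	[number(0)]	false	
range without unit	[number(0)][number(1)]	false	
worded range without unit	[number(0)][range_indicator(1)][number(2)]	false	
unit only	[unit(0)]	false	
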