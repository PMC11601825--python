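unit	context	count	replace_with	remove	invalidate	allow	category
fig	[Fig F2],[Fig F2],[Fig F2], Fig. 6.	285	figure				
figs	Supplementary Figs. 2, 3, 4	40	figure				
figure	figure 6	200				x	location
file	additional file 1	148				x	location
suppl	Suppl Fig. 2	25	supplemental				
supplemental	supplemental figure 2	30				x	modifier
supplementary	supplementary figure 2	60				x	modifier
supporting	Supporting Information S2 Figure	20				x	modifier
additional	additional file 1	150				x	modifier
information	information 9	20				x	location
data	data 1	40				x	location
table	table 4	50				x	location
page	page 11782	100				x	location
p	Abstract & p. 664	60	page				
abstract	Abstract & p. 664	15				x	location
pdb	pdb 1mfd	80				x	pdb
1mfd	pdb 1mfd	1				x	pdb_id
1rzj	pdb 1rzj	1				x	pdb_id
1rzk	pdb 1rzk	1				x	pdb_id
and	[Table T1] and [Fig F1]	500				x	
s2	Supporting Information S2 Figure	5				x	
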