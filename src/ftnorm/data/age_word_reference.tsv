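unit	context	count	replace_with	remove	invalidate	allow	category
old	6-10 week old	710		x			
wk	8-10 wk	57	week				
wks	1-3 wks	12	week				
week	6 week	640				x	unit
weeks	6 to 8 weeks	180	week				
year	30 year	410				x	unit
years	20-67 years	300	year				
month	18 month	120				x	unit
months	18-22 months	100	month				
day	2 day	90				x	unit
days	10-20 days	80	day				
hour	24 hour	35				x	unit
hours	24 hours	30	hour				
h	24 h	20	hour				
mean	mean age = 30 years	55				x	statistical
median	median age 6.3 years	40				x	statistical
age	median age 6.3 years	60		x			
to	6 to 8 weeks	90				x	range_indicator
and	21, 27 and 36 weeks	30				x	
one	one year	4	1				
two	two week	4	2				
three	three day	4	3				
four	four week	4	4				
five	five month	4	5				
six	Six week old	15	6				
seven	seven week	4	7				
eight	eight week	4	8				
nine	nine month	4	9				
ten	ten day	4	10				
eleven	eleven month	2	11				
twelve	twelve week	2	12				
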