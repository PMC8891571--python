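# Boolean dependence relations of the intracellular signaling network.
# Columns: node <TAB> dependence relation <TAB> class
# "External signal" marks receptor/suppressor inputs held fixed during updates.
# Aliases accepted in expressions: ITG = Integrin, cadherin = E-cadherin.
Integrin	External signal	external
RTK	External signal	external
E-cadherin	External signal	external
Wnt	External signal	external
beta-Catenin	( Wnt Or Akt ) And Not cadherin And Not APC	internal
APC	External signal	external
Grb-2/Sos	RTK And Src	internal
Src	FAK	internal
FAK	ITG	internal
Rho-A	FAK	internal
ROCK	Rho-A	internal
Rac-1	PI3K And Not Rho-A	internal
Ras	Grb-2/Sos And Not NF1	internal
NF1	External signal	external
Raf-1	Ras	internal
MEK1/2	Raf-1 Or Rac-1	internal
ERK1/2	MEK1/2	internal
RSK	ERK1/2	internal
TSC	Not RSK Or Not Akt	internal
mTORC	Not TSC	internal
MNK	ERK1/2	internal
eIF4E	MNK	internal
MSK	ERK1/2	internal
Fos	MSK And RSK	internal
Myc	ERK1/2 Or beta-Catenin	internal
PI3K	Ras	internal
Akt	PI3K	internal
eNOS	Akt	internal
NO	eNOS	internal
Caspase	Not NO	internal
Mdm2	Akt	internal
p53	Not Mdm2	internal
Bax	p53	internal
Actin	ROCK Or Rac-1	internal
SNAIL	beta-Catenin	internal
Cell growth	eIF4E Or mTORC	output
Cell proliferation	Fos And Myc	output
Cell apoptosis	Caspase Or p53	output
Cell migration	Actin And SNAIL	output
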