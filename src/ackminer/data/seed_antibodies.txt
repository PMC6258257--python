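anti-GFP
anti-tubulin
anti-actin
anti-myc
anti-HA
anti-FLAG
anti-V5
anti-GST
anti-His
anti-BrdU
anti-tau
anti-synaptotagmin
anti-ubiquitin
anti-lamin
anti-vimentin
anti-desmin
anti-nestin
anti-calbindin
anti-parvalbumin
anti-GFAP
anti-NeuN
anti-MAP2
anti-PCNA
anti-cleaved-caspase-3
anti-phospho-ERK
anti-beta-galactosidase
anti-digoxigenin
anti-bromodeoxyuridine
UL7
CB1
TAG1
4G8
6E10
DM1A
E7
9E10
12CA5
JL-8
YL1/2
TuJ1
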