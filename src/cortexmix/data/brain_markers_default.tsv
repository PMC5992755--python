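gene_symbol	cell_type
RBFOX3	neuron
SNAP25	neuron
SYT1	neuron
STMN2	neuron
SLC17A7	neuron
GABRA1	neuron
NEFL	neuron
SYN1	neuron
GRIN1	neuron
MAP2	neuron
GFAP	astrocyte
AQP4	astrocyte
ALDH1L1	astrocyte
SLC1A2	astrocyte
SLC1A3	astrocyte
GJA1	astrocyte
S100B	astrocyte
ALDOC	astrocyte
MLC1	astrocyte
SOX9	astrocyte
MBP	oligodendrocyte
MOG	oligodendrocyte
MAG	oligodendrocyte
PLP1	oligodendrocyte
CNP	oligodendrocyte
MOBP	oligodendrocyte
CLDN11	oligodendrocyte
SOX10	oligodendrocyte
UGT8	oligodendrocyte
OPALIN	oligodendrocyte
AIF1	microglia
CX3CR1	microglia
P2RY12	microglia
TMEM119	microglia
ITGAM	microglia
TYROBP	microglia
CSF1R	microglia
C1QA	microglia
C1QB	microglia
TREM2	microglia
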