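set,gene
pTE,NR2F2
pTE,SLC38A1
pTE,CCKBR
pTE,SP6
pTE,FYB1
pTE,VGLL1
pTE,CYP11A1
pTE,TINAGL1
pTE,TENM3
pTE,LGALS3
pTE,RHOBTB1
pTE,MRGPRX1
pTE,CBLB
pTE,CCR7
pTE,KCNN4
pTE,GREM2
pTE,MUC15
pTE,CYP19A1
pTE,S1PR2
pTE,PLEKHF1
pTE,PGF
pTE,LCMT1-AS2
pTE,MPP1
pTE,PWWP2B
pTE,GRAMD2B
mTE,CDX2
mTE,RAB25
mTE,ATP6V0A4
mTE,FABP3
mTE,PRSS8
mTE,ATP6V1B1
mTE,GPRC5A
mTE,S100A13
mTE,LRP2
mTE,S100A6
mTE,ENPEP
mTE,FUOM
mTE,TAGLN2
mTE,GALNT10
mTE,SLC12A3
mTE,TMPRSS2
mTE,S100A16
mTE,TAX1BP3
mTE,PCYT2
mTE,LARGE2
mTE,ALPP
mTE,PTGES
mTE,CD53
mTE,DHCR24
mTE,PROM1
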