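# Variant-classification vocabulary for NSSM (non-synonymous somatic
# mutation) calls, MAF dialect.  true = protein-altering (counts toward
# NSSM status and TMB); false = excluded.  Users may supply their own map.
Missense_Mutation: true
Nonsense_Mutation: true
Nonstop_Mutation: true
Frame_Shift_Ins: true
Frame_Shift_Del: true
In_Frame_Ins: true
In_Frame_Del: true
Splice_Site: true
Silent: false
3'UTR: false
5'UTR: false
Intron: false
IGR: false
RNA: false
Translation_Start_Site: false
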