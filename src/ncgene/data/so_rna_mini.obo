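format-version: 1.2
ontology: so-rna-mini
remark: Synthetic miniature of the RNA branch of the Sequence Ontology, shipped for tests, simulation and the worked example. Term accessions follow the real SO where the term exists; the file is NOT the full ontology.

[Term]
id: SO:0000110
name: sequence_feature

[Term]
id: SO:0000673
name: transcript
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000655
name: ncRNA
is_a: SO:0000673 ! transcript

[Term]
id: SO:0001877
name: lnc_RNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0002352
name: sense_overlap_lncRNA
is_a: SO:0001877 ! lnc_RNA

[Term]
id: SO:0002182
name: antisense_lncRNA
is_a: SO:0001877 ! lnc_RNA

[Term]
id: SO:0000276
name: miRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0001244
name: pre_miRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0000253
name: tRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0000252
name: rRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0000650
name: small_subunit_rRNA
is_a: SO:0000252 ! rRNA

[Term]
id: SO:0000651
name: large_subunit_rRNA
is_a: SO:0000252 ! rRNA

[Term]
id: SO:0000275
name: snoRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0000274
name: snRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0000590
name: SRP_RNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0001035
name: piRNA
is_a: SO:0000655 ! ncRNA

[Term]
id: SO:0002095
name: scaRNA
is_a: SO:0000275 ! snoRNA

[Term]
id: SO:0000577
name: centromeric_piRNA_like
is_a: SO:0001035 ! piRNA
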