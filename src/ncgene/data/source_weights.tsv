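# Default source-database weight table for annotation voting.
# Curated expert databases outweigh bulk archives; magnitudes are package
# defaults (the ordering, not the numbers, is the documented constraint).
# columns: source_db	weight	curated
source_db	weight	curated
HGNC	3	1
FLYBASE	3	1
ENSEMBL_GENCODE	3	1
GENCODE	3	1
MGI	3	1
MIRBASE	3	1
GTRNADB	3	1
SNODB	2	1
LNCIPEDIA	1	0
NONCODE	1	0
ENA	1	0
RFAM	1	0
MGNIFY	1	0
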