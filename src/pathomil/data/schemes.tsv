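scheme_name	internal_class	external_class
glas	cancer	Cancer
glas	hyperplastic_polyp	Benign
glas	normal	Benign
crc	cancer	Cancer
crc	hyperplastic_polyp	Benign
crc	normal	Benign
unitopatho	high_grade_dysplasia	High-grade dysplasia
unitopatho	low_grade_dysplasia	Low-grade dysplasia
unitopatho	hyperplastic_polyp	Hyperplastic polyp
unitopatho	normal	Normal
tcga_coad	cancer	Cancer
xu	cancer	Cancer
xu	normal	Normal
aida	cancer	Cancer
aida	high_grade_dysplasia	Dysplasia
aida	low_grade_dysplasia	Dysplasia
aida	hyperplastic_polyp	Hyperplastic polyp
aida	normal	Normal
imp_crc	cancer	High-risk
imp_crc	high_grade_dysplasia	High-risk
imp_crc	low_grade_dysplasia	Low-grade dysplasia
imp_crc	hyperplastic_polyp	Non-neoplastic
imp_crc	normal	Non-neoplastic
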