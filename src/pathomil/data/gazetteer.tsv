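concept_id	preferred_term	synonyms	mapped_class	grade_sensitive
colon:adenocarcinoma	adenocarcinoma	adeno-carcinoma|colorectal adenocarcinoma|infiltrating adenocarcinoma|invasive adenocarcinoma|mucinous adenocarcinoma	cancer	0
colon:carcinoma	carcinoma	cancer|malignant neoplasm|malignancy	cancer	0
colon:high-grade-dysplasia	high-grade dysplasia	high grade dysplasia|severe dysplasia|marked dysplasia|hgd	high_grade_dysplasia	0
colon:low-grade-dysplasia	low-grade dysplasia	low grade dysplasia|mild dysplasia|moderate dysplasia|lgd	low_grade_dysplasia	0
colon:dysplasia	dysplasia	epithelial dysplasia|dysplastic changes	 	1
colon:hyperplastic-polyp	hyperplastic polyp	hyperplastic polyps|hyperplasia|hyperplastic|serrated polyp|hyperplastic mucosa	hyperplastic_polyp	0
colon:adenoma	tubular adenoma	tubulovillous adenoma|villous adenoma|adenomatous polyp|adenoma	 	1
colon:normal-mucosa	normal mucosa	normal colonic mucosa|normal glands|normal colon mucosa|unremarkable mucosa|regular mucosa|no abnormalities	normal	0
colon:margin-of-resection	margin of resection	resection margin|margins of resection	 	0
colon:biopsy	biopsy	biopsies|polypectomy|colon biopsy	 	0
colon:colon	colon	colorectal|large bowel|rectum|sigmoid colon	 	0
colon:mucosa	mucosa	colonic mucosa	 	0
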