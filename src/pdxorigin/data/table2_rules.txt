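# Published 16-rule tissue-of-origin classifier (threshold rules on
# log-scale expression values; applied first-match, inclusive comparisons).
IF ANGPTL4 >= 6.409 AND BHMT2 >= 4.826 THEN Kidney
IF UPK1A >= 6.474 THEN Kidney
IF PAX3 >= 3.401 AND MIA >= 3.562 THEN Skin
IF BHMT2 >= 5.125 AND ANXA10 >= 3.820 THEN Skin
IF PAX8 >= 3.217 AND ADAM10 >= 5.994 THEN Ovary
IF TRADD <= 3.210 AND ASRGL1 >= 6.703 THEN Ovary
IF CPVL >= 7.240 AND CDX1 <= 2.111 THEN Ovary
IF F11R <= 4.935 AND VSNL1 <= 4.528 THEN Soft tissue
IF HSD17B11 <= 5.122 AND ITGA2 <= 6.021 THEN Breast
IF VIM >= 8.697 AND ABHD17C >= 3.622 THEN Breast
IF ADAM28 >= 3.637 AND BTBD6 <= 7.581 THEN Pancreas
IF CXCL5 >= 3.927 AND PCDH1 >= 4.141 THEN Pancreas
IF LOC102724689 >= 7.396 THEN Pancreas
IF MSN >= 5.037 AND PDGFC >= 1.903 AND BCL2L15 <= 5.317 THEN Lung
IF TP73-AS1 >= 3.462 AND ADAM10 >= 6.134 THEN Lung
IF THEN Large intestine
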