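phecode,label,category,exclusion_range_low,exclusion_range_high
562,Diverticulosis and diverticulitis,digestive,555,564
562.1,Diverticulosis,digestive,555,564
562.2,Diverticulitis,digestive,555,564
555.2,Ulcerative colitis,digestive,555,564
558,Noninfectious gastroenteritis,digestive,555,564
560.1,Intestinal obstruction without hernia,digestive,555,564
596,Other disorders of bladder,genitourinary,590,599
596.5,Functional disorders of bladder,genitourinary,590,599
365.1,Open-angle glaucoma,sense organs,360,379
253.3,Pituitary dwarfism,endocrine/metabolic,249,259
182,Malignant neoplasm of uterus,neoplasms,179,190
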