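id	category	text
q1	Basic information	Tell me the basic information about {rs}.
q2	Basic information	What is the genomic location of {rs} in GRCh38 and GRCh37?
q3	Basic information	Which gene is associated with {rs}?
q4	Basic information	What is the reference allele and alternative allele of {rs}?
q5	Basic information	Is {rs} a single nucleotide variant (SNV), insertion, or deletion?
q6	Basic information	What is the minor allele frequency (MAF) of {rs}?
q7	Basic information	Where can I find genomic data for {rs}?
q8	Basic information	What is the Hardy-Weinberg equilibrium status of {rs} in various populations?
q9	Allele frequency and population distribution	Could you show me the allele frequency of {rs} in Japanese populations?
q10	Allele frequency and population distribution	How does the allele frequency of {rs} compare across different populations?
q11	Allele frequency and population distribution	What is the allele frequency of {rs} in East Asian populations?
q12	Allele frequency and population distribution	What is the allele frequency of {rs} in European populations?
q13	Allele frequency and population distribution	What is the allele frequency of {rs} in African populations?
q14	Allele frequency and population distribution	Has {rs} undergone recent positive selection in any population?
q15	Allele frequency and population distribution	Is there any evidence of natural selection acting on {rs}?
q16	Clinical significance	Is {rs} associated with any diseases or clinical conditions?
q17	Clinical significance	What is the clinical significance of {rs} in ClinVar?
q18	Clinical significance	How does the location of {rs} influence the clinical phenotype?
q19	Clinical significance	Is {rs} listed in any GWAS studies?
q20	Clinical significance	Does {rs} increase genetic risk for any diseases?
q21	Clinical significance	How does {rs} influence cancer risk?
q22	Clinical significance	What are the latest clinical findings about {rs}?
q23	Clinical significance	How does {rs} contribute to polygenic risk scores (PRS)?
q24	Pharmacogenomics	Does {rs} influence drug metabolism or response?
q25	Pharmacogenomics	What pharmacogenomic associations exist for {rs}?
q26	Pharmacogenomics	How does {rs} affect the metabolism of alcohol or specific drugs?
q27	Pharmacogenomics	Is {rs} included in any pharmacogenomics guidelines (e.g., PharmGKB)?
q28	Pharmacogenomics	Can {rs} be used as a biomarker for drug response?
q29	Functional impact	How does the {rs} allele affect the structure and function of genes?
q30	Functional impact	What molecular mechanisms are affected by {rs}?
q31	Functional impact	How does {rs} affect transcript expression?
q32	Functional impact	What experimental evidence exists for {rs}’s functional impact?
q33	Functional impact	How does {rs} affect splicing regulation?
q34	Functional impact	Can {rs} be a target for genome editing (CRISPR)?
q35	Functional impact	Is {rs} a dominant or recessive variant?
q36	Evolutionary context	What is the evolutionary background of {rs}?
q37	Evolutionary context	What is the ancestral allele of {rs}?
q38	Evolutionary context	How does {rs} interact with environmental factors?
q39	Evolutionary context	What are the effects of {rs} in cis-acting elements?
q40	Evolutionary context	What selection pressures have acted on {rs} over time?
q41	Comparison with related variants	Tell me about variants that have similar effects to the {rs} variant.
q42	Comparison with related variants	Are there novel variants with similar effects to {rs}?
q43	Comparison with related variants	What haplotypes include {rs}?
q44	Comparison with related variants	How is {rs} different from other known variants in the same gene?
q45	Comparison with related variants	What other missense variants exist in the same gene as {rs}?
q46	Comparison with related variants	Are there any compensatory mutations that counteract the effect of {rs}?
q47	Databases and bioinformatics analysis	What bioinformatics tools can analyze {rs}?
q48	Databases and bioinformatics analysis	What datasets contain information on {rs}?
q49	Databases and bioinformatics analysis	Is {rs} included in any population genomics databases (e.g., gnomAD, 1000 Genomes)?
q50	Databases and bioinformatics analysis	What machine learning models have been used to predict the impact of {rs}?
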