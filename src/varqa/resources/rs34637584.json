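{
  "togovar_id": "tgv45580587",
  "rs_id": "rs34637584",
  "chromosome": "12",
  "position": 40340400,
  "ref": "G",
  "alt": "A",
  "gene_symbol": "LRRK2",
  "clinical_significance": [
    {
      "condition": "Autosomal dominant Parkinson disease 8",
      "interpretations": ["pathogenic", "likely pathogenic"]
    }
  ],
  "most_severe_consequence": {
    "accession": "SO_0001583",
    "label": "missense variant"
  },
  "hgvs": {
    "protein": "ENSP00000298910.7:p.Gly2019Ser",
    "cdna": "ENST00000298910.12:c.6055G>A",
    "genomic": "chr12:g.40340400G>A"
  },
  "predictions": {
    "SIFT": {"score": 0.0, "label": "deleterious"},
    "PolyPhen": {"score": 1.0, "label": "probably damaging"},
    "AlphaMissense": {"score": 0.936, "label": "likely pathogenic"}
  },
  "allele_frequencies": {
    "ToMMo": 0.000028,
    "gnomAD Genomes": 0.00036,
    "gnomAD Exomes": 0.00041,
    "GEM-J WGA": 0.000065,
    "NCBN": 0.00012
  },
  "external_links": {
    "ClinVar": "https://www.ncbi.nlm.nih.gov/clinvar/variation/1940",
    "gnomAD": "https://gnomad.broadinstitute.org/variant/12-40340400-G-A?dataset=gnomad_r4",
    "dbSNP": "https://identifiers.org/dbsnp/rs34637584"
  }
}
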