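# Packaged reference tables

Curated summary tables for the 17-gene *Ciona savignyi* candidate
reference-gene panel screened under temperature and salinity stresses
(45 RNA-Seq samples; 14 genes carried into RT-qPCR validation).

- `table1_candidate_genes.tsv` — per-gene RNA-Seq screening summary:
  Ensembl gene id, name, abbreviation, mean FPKM over the 45 samples,
  and CV% of FPKM (100·SD/mean). The first 11 rows are the novel
  candidates with CV < 16%; the last 6 are traditionally used reference
  genes.
- `table2_qpcr_parameters.tsv` — RT-qPCR panel parameters for the 14
  genes that passed primer validation: amplicon length (bp), measured
  amplification efficiency E (fold/cycle from the standard-curve
  slope), mean Cq and SD of Cq over all samples, CV% of Cq, and the
  rank by CV.

These tables are consumed by consistency tests and by
`scripts/acceptance.py`; they are summaries, not raw data.
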