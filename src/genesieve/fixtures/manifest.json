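{
 "seed": 20230220,
 "n_genes": 12,
 "n_samples": 17,
 "genes": [
  {
   "gene_id": "NUL0000",
   "chromosome": "chr1",
   "label": "unlabeled",
   "n_pairs": 1
  },
  {
   "gene_id": "NUL0001",
   "chromosome": "chr2",
   "label": "unlabeled",
   "n_pairs": 2
  },
  {
   "gene_id": "NUL0002",
   "chromosome": "chr3",
   "label": "unlabeled",
   "n_pairs": 1
  },
  {
   "gene_id": "NUL0003",
   "chromosome": "chr1",
   "label": "unlabeled",
   "n_pairs": 1
  },
  {
   "gene_id": "NUL0004",
   "chromosome": "chr2",
   "label": "unlabeled",
   "n_pairs": 2
  },
  {
   "gene_id": "NUL0005",
   "chromosome": "chr3",
   "label": "unlabeled",
   "n_pairs": 1
  },
  {
   "gene_id": "POS0000",
   "chromosome": "chr1",
   "label": "positive",
   "n_pairs": 2
  },
  {
   "gene_id": "POS0001",
   "chromosome": "chr2",
   "label": "positive",
   "n_pairs": 1
  },
  {
   "gene_id": "POS0002",
   "chromosome": "chr3",
   "label": "positive",
   "n_pairs": 1
  },
  {
   "gene_id": "POS0003",
   "chromosome": "chr1",
   "label": "positive",
   "n_pairs": 2
  },
  {
   "gene_id": "POS0004",
   "chromosome": "chr2",
   "label": "positive",
   "n_pairs": 2
  },
  {
   "gene_id": "POS0005",
   "chromosome": "chr3",
   "label": "positive",
   "n_pairs": 1
  }
 ]
}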