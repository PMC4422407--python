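# phosmoca

Comparative-genomics analysis of **phos**phorylation-**mo**tif
**c**onservation **a**cross eukaryote genomes.

Protein kinases recognise short positional sequence motifs around the
serine/threonine/tyrosine residues they phosphorylate — `S/T-P` for the
proline-directed CMGC kinases (MAPK, CDK, GSK), `R-X-X-S/T` and related
basophilic patterns for AGC/CAMK kinases (PKA, PKC, AKT).  Whether the
phosphosites carrying a motif are evolutionarily retained, beyond what
bare S/T/Y residues manage, is a strong hint that the motif marks
functional signalling.  `phosmoca` is a library (plus a thin `phosmoca`
CLI) for asking exactly that question: it matches motif patterns at known
and potential human phosphosites, projects each site through
ortholog-cluster multiple alignments into eight non-human genomes
(*S. cerevisiae*, *S. pombe*, *C. elegans*, *D. melanogaster*,
*D. rerio*, *C. familiaris*, *M. musculus*, *P. troglodytes*), and
summarises the outcome per motif as a **conservation index**

```
CI = Σ_{q ∈ G} (C_q − R_q)
```

where, for genome *q*, `C_q` is the fraction of the motif's human sites
whose full motif window is precisely matched in the aligned ortholog, and
`R_q` is the background conservation of the acceptor residue type across
all S/T/Y residues of the phosphoprotein set.  Positive CI means the
motif's sites are retained above residue background; the human reference
genome contributes exactly zero.

On top of the CI the package reproduces the study's downstream analyses:

- paired comparison of known-site vs potential-site CIs (scatter,
  Pearson correlation, counts above/below the `y = x` diagonal);
- CI-rank binning of motifs in classes of ten, counting proline-directed
  vs basophilic patterns per class;
- kinase-substrate group/family fractions per motif, kinase-group
  substrate CIs, and per-genome kinome-expansion tables;
- hypergeometric term enrichment of motif protein sets with
  Benjamini–Hochberg control (cutoffs FDR < 0.01 and p < 0.01);
- a permutation statistic for excess interactions among same-motif
  proteins in a protein-interaction network.

A first-class synthetic-data module generates ortholog families with
planted, per-genome conservation probabilities and closed-form expected
CIs, so every stage is testable without any database download.

## Worked example

`examples/02_conservation_index.py` plants `R-X-X-S/T` sites conserved at
0.8 per genome against a 0.5 background in 300 families and runs the full
chain:

```
planted sites: 600
  sce: C=0.775  R=0.507  term=+0.268
  spo: C=0.805  R=0.517  term=+0.288
  cel: C=0.798  R=0.519  term=+0.279
  dme: C=0.780  R=0.511  term=+0.269
  dre: C=0.810  R=0.507  term=+0.303
  cfa: C=0.760  R=0.517  term=+0.243
  mmu: C=0.808  R=0.504  term=+0.304
  ptr: C=0.805  R=0.512  term=+0.293
CI estimate        : 2.248
closed-form truth  : 2.283
ideal 8*(0.8-0.5)  : 2.400
```

The estimate tracks the exact closed-form expectation of the generator;
the small gap to the ideal `8 × 0.3 = 2.4` is the documented contribution
of planted acceptors to the background rate (see `docs/methods.md`).
The other examples cover the motif grammar, the known-vs-potential
comparison, kinase analyses, enrichment/network statistics, and the full
eight-stage pipeline:

```bash
phosmoca simulate --config config.yaml --out data/
phosmoca pipeline --config config.yaml --out results/
```

Each stage writes deterministic TSVs (fixed sort keys, 6-significant-digit
floats); `manifest.json` records the config hash, seed, and per-stage row
counts, and reruns are byte-identical.

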