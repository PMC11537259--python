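# xlquant

Quantitative cross-linking mass spectrometry (XL-MS) toolkit for isobaric
(TMTpro 18-plex) reporter-ion quantification of cross-linked peptides:

- **spectra_io** — MGF reading/writing with verbatim titles and sorted peaks.
- **reporter_quant** — ppm-tolerance matching of low-mass reporter ions
  against a channel reference table (built-in TMTpro 18-plex or any plex
  from file), multi-peak summation, per-spectrum extraction table, and an
  optional (beta, off by default) channel-total normalisation.
- **plink_io** — parser/writer for hierarchical pLink2-style cross-linked
  peptide CSVs (protein headers → peptide headers → PSM rows), spectrum-title
  matching to attach reporter intensities, and channel-wise roll-up to
  peptide and protein headers.
- **linkmap** — canonical protein residue-pair mapping, intra/inter
  classification, the long loop-link rule (≥5 AA sequence separation),
  shared-peptide exclusion, seeded shuffled-decoy (entrapment) FASTA
  construction, and the CSM table for external PPI-FDR tools (xiFDR).
- **quant_matrix** — residue-pair aggregation, sample normalisation to the
  maximum total, row-mean scaling + log2, and replicate CV% summaries.
- **structure_overlay** — CA–CA Euclidean distances of intralinks on
  AlphaFold-style models (pLDDT from the B-factor column), per-protein
  distance profiles with the <20 Å / >20 Å classification, and disorder
  region overlap.
- **genostruct** — per-intralink OLS regression of cross-link on protein
  abundance profiles (residuals = net structural differences), missense
  mutation/cross-link interval overlap, and event selection
  (|residual| > 0.4 and > 2×SD, discretised to −1/+1).
- **fixtures** — fully synthetic, seeded, ground-truthed input bundles
  (FASTA, pLink-style CSV, MGF with planted reporter ions, protein matrix,
  mutation/disorder tables, toy PDB models, truth tables).

## CLI

Each stage is a subcommand of `xlquant`; every run writes a resolved
`*.config.yaml` beside its outputs.

```sh
xlquant simulate --seed 7 -o fixtures/                 # synthetic bundle
xlquant extract --mgf-dir fixtures/mgf --plex tmtpro18 --tol-ppm 15 -o table.tsv
xlquant map --plink fixtures/plink_results.csv --reporter-table table.tsv -o annotated.csv
xlquant links --plink annotated.csv --fasta fixtures/proteome.fasta \
    --decoy-seed 7 --xifdr-out xifdr_input.tsv -o pairs.tsv
xlquant quant --annotated annotated.csv --fasta fixtures/proteome.fasta \
    --replicate-map fixtures/replicate_map.tsv -o matrix.tsv
xlquant overlay --pairs pairs.tsv --models fixtures/models \
    --disorder fixtures/disorder.tsv -o overlay.tsv
xlquant regress --xl matrix.tsv --protein fixtures/protein_matrix.tsv \
    --mutations fixtures/mutations.tsv --gene-map fixtures/gene_map.tsv \
    --replicate-map fixtures/replicate_map.tsv -o events.tsv
```

`xlquant all --seed 7 -o run/` chains every stage on a fresh simulated
bundle; re-running with the same seed reproduces the outputs byte for byte.

## Notes

- Channel-total normalisation (`xlquant extract --normalize`) assumes equal
  total signal per channel and is unsuitable for fractionated or
  intentionally unbalanced designs; it is therefore off by default.
- Rows containing a zero intensity in any channel are dropped (with a
  logged count) before log2 scaling rather than pseudo-counted.
- Spectrum-title matching defaults to exact (whitespace-stripped) equality;
  a regex rule can reduce both sides to a `file.scan.charge` core when the
  MGF converter and the search engine disagree on title formats.
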