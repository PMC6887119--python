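# ribopath

Analysis pipeline for mapping an mRNA-binding channel on the small ribosomal
subunit and quantifying its impact on translation:

- **`ribopath.rtts`** — reverse-transcriptase termination (RT-stop) site
  calling on 18S rRNA from aligned reads (the crosslinked residue is the
  nucleotide 5'-adjacent to each read's 5' end), top-site ranking, helix
  (ES6S) interval annotation, region fractions and profile contrasts.
- **`ribopath.te`** — polysome-profiling translation efficiency: spike-in
  median-of-ratios normalization, TE = polysomal/monosomal abundance per
  condition, log2 FC TE, per-gene testing (moderated t by default; Welch and
  permutation variants) with BH adjustment, and TE_down / TE_up / unchanged
  classification at the asymmetric thresholds (>1 / <-0.7).
- **`ribopath.utr`** — 5' UTR features: length, G+C percent, G-quadruplex
  (GxN1-12)4 scanning (G3 and G2 variants), (GGC/A)>=4 tandem repeats, a
  Nussinov maximum-pairing structure proxy (external folding energies
  ingestible), 5' TOP flagging, Mann-Whitney U (exact small-sample branch),
  Pearson chi-square motif enrichment and feature PCA.
- **`ribopath.kinetics`** — full-translation time (FTT) estimation from
  continuous luciferase recordings, FTT-vs-UTR-length slopes, endpoint fold
  inhibition, median-effect dose-response fits and the Chou-Talalay
  combination index.
- **`ribopath.geometry`** — linear mRNA path model on the 40S solvent side
  (4.5 A/nt rise, +11 entry-channel origin) and oligo-rRNA duplex mapping by
  longest contiguous antiparallel complementarity.
- **`ribopath.simulate`** — seeded generators for every input (RTTS reads
  with planted crosslink sites, negative-binomial count matrices with planted
  TE shifts and spike-in size factors, UTR sets with planted motifs,
  luminescence curves with known onsets, median-effect dose-response tables),
  each returning a ground-truth table.

## CLI

All functionality is exposed through the `ribopath` entry point:

```sh
# generate synthetic inputs with ground truth
ribopath synth --spec spec.yaml --seed 1 --out data/

# RT-stop site calling: site table, bedGraph, BED of top-k sites
ribopath rtts --alignments data/rtts.sam --ref-length 1869 --top 18

# translation-efficiency table
ribopath te --counts data/counts.tsv --design data/design.tsv \
    --alpha 0.05 --down 1.0 --up -0.7

# UTR features, group statistics and motif enrichment
ribopath utr --fasta data/utrs.fasta --te-table te_table.tsv

# kinetics
ribopath ftt --curves curves.tsv
ribopath synergy --doses doses.tsv

# geometry
ribopath geometry --positions positions.tsv --rise 4.5 --origin 11
ribopath duplex --oligo oligo.fasta --rrna rrna.fasta
```

`synth` takes a YAML mapping generator names (`rtts`, `counts`, `utrs`,
`curve`, `dose_response`) to their keyword parameters; see the dataclasses in
`ribopath.simulate` for the fields.

## Conventions

Coordinates are 1-based inclusive internally; BED/bedGraph exports are
0-based half-open. Sequences may be DNA or RNA (U and T are equivalent).
Positive log2 FC TE means the treatment reduced translation efficiency.
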