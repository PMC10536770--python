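# genefam

Gene-family evolution along species trees: forward simulation with logged
truth, gene-tree building, gene-tree/species-tree reconciliation,
duplication-mechanism classification from genomic coordinates, and codon
branch-model selection tests.

## What it does

- **`genefam.synthetic`** — simulates a gene family down a rooted species
  tree: tandem/inverted/segmental/transposed duplications, atomic
  triplications, losses, and whole-genome duplication/triplication (WGD/WGT)
  branches with partial retention. Every surviving copy gets genomic
  coordinates consistent with its generating mechanism, and codon sequences
  are evolved under a branch-class-specific dN/dS model. Named presets:
  `toy4`, `core16`, `brassicaceae_like` (29 species, basal lineage splitting
  before the MAF1/2/3–MAF4/5 tandem duplication, WGT branches, one FLC-like
  plus one MAF-like root gene).
- **`genefam.gene_tree`** — deterministic two-threshold alignment trimming,
  Kimura-corrected protein distances, Saitou–Nei neighbor joining, column
  bootstrap support, outgroup rooting.
- **`genefam.reconciliation`** — LCA mapping, duplication flags, per-edge
  parsimony loss counts, ancestral copy-number reconstruction with flow
  conservation checks.
- **`genefam.events`** — assigns each inferred duplication a mechanism from
  the coordinates of its closest same-species witness pair (tandem ≤ 100 kbp
  same strand; inverted ≤ 100 kbp opposite strands; segmental, same scaffold
  beyond that, low-confidence in the 100–500 kbp gray zone; transposed when
  no same-scaffold witness exists), collapses nested tandem pairs into
  triplications, relabels cross-scaffold duplications on annotated WGD/WGT
  branches as polyploidy retentions, and tabulates per-branch events and
  per-species copy numbers.
- **`genefam.selection`** — GY94-style 61×61 codon rate matrix with F3x4
  frequencies, Felsenstein-pruning likelihood with analytic branch-length
  gradients, multi-start (ω ∈ {0.5, 1, 2}) bounded quasi-Newton fitting of
  the one-ratio model M0 and the branch model Mb (classes: background,
  MAF4/5, MAF1/2/3, FLC s.str.), and the chi-square likelihood-ratio test.
- **`genefam.cli`** — orchestrates the stages through intermediate files.

## CLI

```bash
genefam simulate --preset brassicaceae_like --seed 7 --out out/sim
genefam tree      --alignment out/sim/cds.fasta --out out/tree --bootstrap 100 --seed 7
genefam reconcile --gene-tree out/sim/gene_tree.nwk --species-tree out/sim/species_tree.nwk --out out/rec
genefam classify  --gene-tree out/sim/gene_tree.nwk --species-tree out/sim/species_tree.nwk \
                  --loci out/sim/loci.tsv --out out/cls
genefam select    --alignment out/sim/cds.fasta --tree out/sim/gene_tree.nwk --out out/sel
genefam all       --preset core16 --seed 7 --out out/run          # whole pipeline
genefam all       --config cfg.json                                # JSON config, flags override
```

Exit codes: 0 success, 2 validation error, 1 runtime error. `all` writes a
`manifest.json` with the config snapshot, seed, version, and per-stage wall
times; every stage reads and writes plain-text formats (FASTA, newick, TSV),
so real data can enter at any stage. Branch classes travel in newick as a
`#classname` suffix on the branch's child label, e.g. `(a#FLC_sstr:0.1,b:0.2)`.

## File formats

- Loci table (TSV): `gene_id species scaffold start end strand exons [cds]`,
  1-based inclusive on disk, 0-based half-open in memory; exons are
  semicolon-joined `start-end` pairs. Optional GFF3 export.
- Event log (TSV): `type branch time parent_gene child_genes`.
- Selection table (TSV): `model lnL np omega0..omega3 kappa 2dLnL dnp p`.

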