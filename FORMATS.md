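# File formats

All inputs and outputs are plain text.  Report TSVs begin with two comment
lines: `# wrkykit <version>` and `# columns: <tab-joined names>`.

## Inputs

### Protein FASTA
Standard multi-record FASTA, wrapped or unwrapped.  Sequences use the
20-letter amino-acid alphabet; `X` is tolerated but never matches a motif
literal.

### Reference panel FASTA
Headers are `>id|subgroup` where subgroup is one of
`I IIa IIb IIc IId IIe III`.  Sequences are WRKY domain regions
(heptapeptide through zinc-finger end).  The packaged default lives at
`src/wrkykit/data/reference_panel.fasta` and may be replaced via
`classify --panel`.

### Genome FASTA + GFF3
GFF3 with `gene`, `mRNA`, `exon`, `CDS` features (1-based closed
coordinates, converted to 0-based half-open internally).  A gene carrying
`CDS` children without an `mRNA` is treated as a single-transcript gene.

### Cis-element catalog TSV
Three tab-separated columns: `element_id`, IUPAC pattern, category.
`#` starts a comment.  PLACE's native flat format is not parsed; convert
entries to this layout first (one element per line).

### Ct table TSV
Columns `gene`, `condition`, `replicate`, `ct`.  One reference gene and one
control condition are named on the command line.

### Counts table TSV
Columns `gene`, `sample`, `count`, `length` (gene length in nt).

### Run configuration JSON
Serialized `RunConfig`; every field has a default equal to the pipeline's
standard value (window 1000, min_sites 3, up 1.5, down 0.66, alpha 0.05,
FPKM validity 10, deviation probability 0.8, identity floor 0.35, spacer
ranges [3,7]/[5,27], linker_max 120, gap open/extend 10/1, 1000 bootstrap
replicates, seed 0).

## Outputs

| command   | columns / content |
|-----------|-------------------|
| identify  | `protein_id  length  n_domains  motifs  signatures` (slash-joined per domain) |
| classify  | `protein_id  group  basis  best_reference  identity` |
| tree      | newick; internal node labels are bootstrap support percentages |
| promoters | FASTA, ids `<gene_id>\|promoter\|<length>` |
| scan      | `gene_id  element_id  category  strand  offset` |
| targets   | `gene_id  wbox_count  tier1  tier2  tier3  positions` (offsets sorted ascending, comma-joined) |
| structure | `gene_id  n_exons  n_introns` |
| qpcr      | `gene_id  condition  fold_change  p_value  call`; optional rq TSV `gene_id  condition  rq` |
| rnaseq    | `gene_id  fold_change  deviation_probability  call` (`invalid` rows have empty numbers) |
| simulate  | dataset files in the formats above plus `*_truth.json` ground truth |

## Conventions

- Motif hit offsets are negative and ATG-relative: `-1` is the base
  immediately upstream of the `A` of `ATG`; a hit's offset is the position
  of its window's 5'-most base in gene orientation, so the promoter
  subsequence at `[offset, offset + len)` matches the stated strand's
  pattern.  Reverse-strand hits match the pattern's reverse complement.
- Promoters shorter than the window are scanned as-is and flagged
  truncated, never discarded.
- Zinc-finger signatures render as `C-X{a}-C-X{b}-HX{T}` with terminal
  `T` in `{H, C, Y}`; CCHH/CCHC/CCHY typing follows the terminal residue.
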