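# wrkykit

A tested, reusable pipeline for genome-wide WRKY transcription-factor
family surveys:

- **Domain detection** (`wrkykit.domains`) — find canonical (`WRKYGQK`) and
  variant heptapeptide motifs (anchored W/K/Y, bounded Hamming distance) and
  parse the downstream zinc finger into a `C-X{a}-C-X{b}-HX{T}` spacing
  signature (CCHH / CCHC / CCHY typing); assemble validated domains with
  N/C labels for two-domain proteins.
- **Classification** (`wrkykit.classify`) — group I by two domains, group
  III by a CCHC finger, and subgroups IIa–IIe vs the non-group (NG) by
  nearest-reference identity against a replaceable subgroup-labelled panel.
- **Phylogenetics** (`wrkykit.align`, `wrkykit.phylo`) — affine-gap global
  alignment (BLOSUM62), progressive MSA (UPGMA guide tree, profile–profile
  merge), Saitou–Nei Neighbor-Joining (exact on additive matrices) and
  seeded column-bootstrap support values.
- **Promoter regulome** (`wrkykit.regulome`) — extract up-to-1-kb upstream
  regions from genome+GFF3, scan both strands for the W-box (`YTGACY`) and
  any IUPAC cis-element catalog, call target genes by site-count tiers
  (≥1/≥2/≥3), and summarize exon/intron structure.
- **Expression** (`wrkykit.expression`) — 2^−ΔΔCt relative expression from
  Ct tables, Dunnett many-to-one tests (seeded Monte Carlo), FPKM from
  count tables, and up/down calls (fold > 1.5 / ≤ 0.66 with p < 0.05, or
  FPKM-validity + bootstrap deviation probability ≥ 0.8).
- **Synthetic data** (`wrkykit.simulate`) — seeded generators for proteomes
  with planted domains, genomes with motif-free-certified promoters and
  planted elements, Ct tables and negative-binomial count tables, each with
  ground truth sufficient to verify every stage offline.

## CLI

`wrkykit` (or `python -m wrkykit.cli`) exposes one subcommand per stage;
`--seed`, `--config` and `--log-level` are global.  See FORMATS.md for all
file layouts.

```sh
wrkykit --seed 1 simulate --kind proteome --out-dir sim/
wrkykit identify  --proteins sim/proteome.fasta --out domains.tsv
wrkykit classify  --proteins sim/proteome.fasta --out groups.tsv
wrkykit tree      --proteins sim/proteome.fasta --out tree.nwk --bootstrap 1000
wrkykit --seed 1 simulate --kind genome --out-dir sim/
wrkykit promoters --genome sim/genome.fasta --gff sim/genes.gff3 --out promoters.fasta
wrkykit scan      --genome sim/genome.fasta --gff sim/genes.gff3 --out hits.tsv
wrkykit targets   --genome sim/genome.fasta --gff sim/genes.gff3 --out targets.tsv
wrkykit structure --gff sim/genes.gff3 --out structure.tsv
wrkykit qpcr      --ct ct.tsv --reference-gene ACT --control-condition 0h --out de.tsv
wrkykit rnaseq    --counts counts.tsv --control-samples C1,C2,C3 \
                  --treated-samples T1,T2,T3 --out rnaseq.tsv
```

## Notes

- The packaged reference panel is illustrative and user-replaceable
  (`classify --panel my_panel.fasta`); subgroup calls depend on the panel.
- "Deviation probability" for FPKM calls is a seeded bootstrap
  direction-consistency probability over replicate resamples.
- All generators and stochastic procedures are deterministic given a seed.
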