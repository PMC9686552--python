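# exomir

A small-RNA sequencing analysis pipeline for miRNA expression profiling,
built as independent, tested stages:

1. **preprocess** — 3' adapter trimming, junk/low-complexity filtering
   (length, 80%-single-base, 3N, AC-only, GT-only, dimer/trimer repeats),
   read collapsing into unique 18–26 nt tags with per-sample copy numbers,
   and contaminant filtering (rRNA/tRNA/snRNA/snoRNA/repeat/mRNA) with
   exact or 1-substitution matching on either strand.
2. **identify** — tags are mapped ungapped (≤1 substitution, bounded 5'/3'
   end shifts) to precursor references to call known matures and opposite-arm
   (novel 5p/3p) products, then to other-species precursors with genome
   confirmation, and finally scanned against the genome; unexplained tags
   with genomic loci become novel-miRNA candidates.
3. **hairpin** — candidate loci are folded (built-in maximum-pairing
   fallback, pass-through dot-bracket files, or the external ViennaRNA
   bindings when installed) and screened with eleven secondary-structure
   criteria (stem pairs ≥ 16, energy ≤ −15 kcal/mol, hairpin span ≥ 50 nt,
   terminal loop ≤ 20 nt, bulge-size/asymmetry/pairing constraints on the
   mature region, ≥ 80% of the mature inside the stem, ...).
4. **normalize** — median-reference regression normalization: a common
   sequence set defines a log2-median reference; per-sample OLS on the
   |Δlog2| < 2 subset yields an arithmetic correction factor
   `f = 2^(x_mid − y_mid)` applied multiplicatively.
5. **diffexp** — pooled-variance t-tests on log2(norm value + ε); a miRNA is
   differentially expressed when |log2 fold change| ≥ 1 and p < 0.05; exports
   volcano, heatmap (row-z-scored), and up/down summary tables; BH FDR is
   reported but never gates calls.
6. **targets** — seed-match scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer) with a
   transparent two-channel scorer; predictions pass only the dual-threshold
   intersection: context-like score ≥ 50 AND duplex energy < −10.
7. **enrich** — upper-tail hypergeometric GO/KEGG enrichment with
   Benjamini–Hochberg correction per namespace.
8. **milkstats** — two-sample trait comparisons (Student and Welch) from raw
   values or mean ± SD summaries with significance marks.

A first-class `synthetic_data` module generates every input the pipeline
needs — stem-loop precursor references, contaminants, a toy genome with
planted novel hairpin loci, per-sample FASTQ reads with planted categories
(end variation, substitutions, adapter dimers, junk), two-group count
matrices with planted fold changes, UTRs with planted target sites, and a
hairpin-criteria structure fixture suite — all bit-reproducible from a seed
and accompanied by machine-readable truth tables.

## CLI

```sh
# generate a complete synthetic fixture with truth tables
exomir simulate --out fixture --seed 1 --reads 2000

# run the whole cascade (resumable; reruns are byte-identical)
cat > config.yaml <<EOF
seed: 1
fixture: fixture
EOF
exomir run-all --config config.yaml --out results

# or stage by stage
exomir preprocess --manifest fixture/reads/manifest.tsv \
    --contaminants fixture/refs/contaminants.fa --out pre
exomir identify --tags pre/tags.tsv --hairpin fixture/refs/hairpin.fa \
    --mature fixture/refs/mature.fa --coords fixture/refs/coords.tsv \
    --genome fixture/refs/genome.fa --out ident
exomir hairpin --windows ident/candidate_windows.tsv --backend builtin --out hp
exomir normalize --counts fixture/counts.tsv --out norm
exomir diffexp --normalized norm/normalized.tsv \
    --groups A:A1,A2,A3 --groups B:B1,B2,B3 --out de
exomir targets --results de/results.tsv --mature fixture/refs/mature.fa \
    --utrs fixture/utrs.fa --out tg
exomir enrich --predictions tg/predictions.tsv \
    --annotations fixture/annotations.tsv --utrs fixture/utrs.fa --out en
exomir milkstats --table milk.tsv --variant student --out milk_cmp.tsv
```

Every stage writes TSV outputs plus a `stage_manifest.json` with input
hashes and parameters; rerunning a stage with unchanged upstream hashes
skips recomputation. Logs go to stderr, results only to files.

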