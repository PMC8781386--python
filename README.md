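# tandemshm

Tandem substitution analysis of somatically hypermutated immunoglobulin
V regions.

Somatic hypermutation mostly creates single nucleotide substitutions (SNS),
but runs of adjacent substituted bases also occur. Some of those runs are
genuine single-event tandem substitutions; others are coincidental clusters
of independent SNS. This package provides a tested pipeline that:

* reads germline V alleles (FASTA) and germline-aligned rearrangement
  records (AIRR-style TSV),
* collapses clonal expansions (gene-level V/D/J + CDR3 length key,
  single-linkage clustering at ≥95% CDR3 identity, least-mutated
  representative) and filters by V-region mutation load (0 < m/L ≤ 5%),
* calls all maximal substitution runs with 1-nt germline context,
* corrects observed tandem counts with a Monte-Carlo null: germline
  sequences are re-mutated in silico with per-position SNS frequencies and
  target-base distributions from the data, matching each sequence's
  mutation load exactly; the simulated cluster counts give per-run-length
  means, z-scores and corrected counts/incidences,
* classifies tandem dinucleotide substitutions as inversions,
  juxtalocations of the 5′/3′ base, or other; annotates codon slot,
  amino-acid effect, AID hotspot motifs (WRCY/WA/RCG, both strands) and
  germline-context containment; builds 144-cell dinucleotide tables and
  COSMIC-style DBS-78 catalogs with cosine comparison against supplied
  signatures,
* scores per-codon-position mutational resistance (observed minus expected
  synonymous fraction of SNS) and regresses tandem counts on it with a
  quasi-Poisson model,
* generates synthetic repertoires with known ground truth (hotspot-biased
  SNS, injected true tandems at a controllable rate, clonal duplicates) so
  everything is testable offline.

## Command line

All stages are exposed via the `tandemshm` entry point:

```bash
# synthetic repertoire with 5% true tandem events
tandemshm synth --n 500 --theta 0.05 --seed 1 --out-dir work/

# call substitution events
tandemshm call --germlines work/germlines.fasta \
    --rearrangements work/rearrangements.tsv --out-dir work/

# Monte-Carlo null and corrected incidences
tandemshm simulate-null --germlines work/germlines.fasta \
    --rearrangements work/rearrangements.tsv \
    --reps 10000 --seed 1 --out-dir work/

# tandem classification, motif/effect annotation, dinucleotide table
tandemshm classify --events work/events.tsv \
    --germlines work/germlines.fasta --out-dir work/

# resistance track and quasi-Poisson fit
tandemshm score --germlines work/germlines.fasta \
    --rearrangements work/rearrangements.tsv --out-dir work/

# cosine similarity against a DBS-78 signature CSV
tandemshm signature --events work/events.tsv --dbs signatures.csv --out-dir work/

# full pipeline (here on a synthetic repertoire), JSON report
tandemshm run --synthetic-theta 0.05 --synthetic-n 500 \
    --reps 10000 --seed 1 --out-dir work/
```

`tandemshm run` also accepts `--config config.toml` (or `.yaml`) mirroring
every flag; explicit flags override the file.

## Layout

| module | contents |
| --- | --- |
| `tandemshm.io_model` | domain types; FASTA/TSV/CSV/JSON readers and writers; DBS-78 classes |
| `tandemshm.selection` | clonotype keys, clonal collapse, mutation-load filter and bins |
| `tandemshm.calling` | maximal-run substitution calling, run-length tables, Ts/Tv |
| `tandemshm.tandems` | tandem classification, effects, motifs, context, DBS-78, cosine |
| `tandemshm.nullsim` | position profiles, Monte-Carlo null, corrected incidence |
| `tandemshm.scoring` | codon enumeration, resistance track, quasi-Poisson regression |
| `tandemshm.synth` | toy alleles, ground-truth repertoire simulation, clonal expansion |
| `tandemshm.pipeline` / `tandemshm.cli` | full-pipeline orchestration and the `tandemshm` CLI |

Coordinates are 0-based, half-open, in ungapped germline space; IMGT `.`
gap columns carry no position number. Sequence ends use the flank sentinel
`-`; observed `N` bases are never counted as mutated and split runs.
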