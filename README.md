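# toxdup

A toolkit for detecting toxin-gene duplications in a predicted proteome:

* **Profile-HMM clustering** — builds one profile HMM per sequence, scores
  all pairs by local five-state HMM–HMM alignment (MM/MI/IM/DG/GD),
  converts bit scores to E-values through a Gumbel null fitted to
  shuffled-model decoys, and iteratively merges the lowest-E pair while
  `E < cutoff` (default `1e-20`).  Groups with two or more members are
  reported as likely gene duplicates; everything ends up on a UPGMA
  relationship tree (Newick).
* **Five-stage candidate-toxin filter** — consumes precomputed homology hit
  tables (13-column tab-separated: the classic 12-column tabular dialect
  plus a query-coverage column) and annotation tables, and applies, in
  order: initial e-value cut (`< 1e-5`), strict/relaxed (top-5) reciprocal
  best hit to the toxin database with query coverage `> 70 %`, reciprocal
  support in both a full and a taxon-restricted database (`e < 1e-5`),
  score consistency against non-toxin subjects, structural exclusion
  (`>= 2` transmembrane segments, bad domain architecture, excluded GO
  terms), and own-genome support (coverage `> 75 %`, `e < 1e-20`).  All
  thresholds are strict; boundary values fail.
* **Proteome evidence** — in-silico tryptic digestion (cleave after K/R
  unless before P, up to three missed cleavages) and a detection rule of at
  least two distinct peptides at ungapped identity `> 95 %`, plus a
  contaminant screen against a second proteome's hit table.
* **Tajima's D** — the neutrality statistic with all intermediate
  quantities, computed on gap/ambiguity-free columns of a group alignment.
* **Synthetic fixtures** — seeded generators for families of duplicated
  sequences, neutral-coalescent alignments, staged pipeline hit tables with
  planted outcomes, and peptide observations, each emitting its ground
  truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (DP versus a
brute-force path-enumeration oracle, Gumbel parameter recovery, clustering
recovery over 20 seeded simulations, report arithmetic, Tajima's D against
a direct-formula oracle and a neutral coalescent, the planted pipeline
fixture with boundary-value checks, digest properties, and CLI
byte-determinism).

## Command line

Everything is exposed through one entry point:

```sh
toxdup simulate families --n-families 3 --members 4 --seed 7 --out-dir sim
toxdup cluster --in sim/families.fasta --cutoff 1e-20 --seed 7 --out-dir run
# -> run/groups.tsv, run/tree.nwk, run/merge_log.tsv, run/summary.json

toxdup simulate pipeline --n-true 12 --n-decoys 40 --seed 7 --out-dir simp
toxdup toxfilter \
    --hits-toxdb simp/hits_toxdb.tsv --hits-toxdb-reverse simp/hits_toxdb_rev.tsv \
    --hits-fulldb simp/hits_fulldb.tsv --hits-fulldb-reverse simp/hits_fulldb_rev.tsv \
    --hits-cniddb simp/hits_cniddb.tsv --hits-cniddb-reverse simp/hits_cniddb_rev.tsv \
    --hits-selfgenome simp/hits_selfgenome.tsv --annotations simp/annotations.tsv \
    --out-dir filt
# -> filt/candidates.tsv, filt/report.tsv

toxdup tajima --alignment group.afa
toxdup detect --peptides peptides.txt --proteome proteome.fasta --out-dir det
toxdup report --groups run/groups.tsv --detected det/detected.tsv
```

Every subcommand honours `--seed`, writes a `manifest.json` (inputs,
configuration, version) and is byte-deterministic given the same inputs and
seed.  `toxfilter --config file` accepts `key=value` overrides of the
pipeline thresholds; command-line flags win over the config file.

## Layout

```
src/toxdup/
  formats.py    FASTA / hit-table / annotation / peptide / Newick I/O
  hmm.py        profile-HMM construction and shuffling
  compare.py    HMM–HMM local alignment, Gumbel calibration, E-values
  cluster.py    iterative duplication clustering, UPGMA trees, reports
  pipeline.py   the five-stage candidate-toxin filter
  evidence.py   tryptic digestion, peptide identity, detection, contaminants
  neutrality.py Tajima's D
  simulate.py   seeded synthetic fixtures with planted truth
  cli.py        click entry point (`toxdup`)
```
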