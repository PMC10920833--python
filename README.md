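# gtclan

Tools for classifying extremely divergent bacterial polysaccharide
polymerases (Wzy-type BP-Pols) and relating them to the glycan repeat units
they polymerize:

- **Two-stage family clustering** — a sequence similarity network (SSN) over
  pairwise bit scores gives clusters; per-cluster frequency profiles are
  compared all-vs-all (directionally) and thresholded into superclusters;
  sufficiently large superclusters become families. Adapters ingest real
  BLAST outfmt-6 and profile-score TSVs so the published thresholds
  (110 / 160 / >150 members) can be applied to imported data; internal
  stand-in scorers ship with separately calibrated defaults.
- **Hierarchical trees** — distances from a Scoredist-style transform
  (normalized to the shorter sequence length) are embedded with metric-matrix
  distance geometry, joined by nearest-neighbor joining with centroid
  averaging, and recursively re-embedded per subtree; exported as newick.
- **Glycan backbone similarity** — IUPAC-condensed-style repeat-unit strings
  are parsed, reduced to backbone geometric tokens (P/F/L ring class, carbon
  indices, U/D/N oxygen orientations), and scored pairwise outward from the
  polymerase bond subsites (−1/+1), with re-use–guarded extension. Reaction
  stereochemistry (retaining/inverting) is inferred from the axiality of the
  polymerase bond.
- **Synthetic data** — seeded generators for protein families with controlled
  within-family identity, glycan repeat-unit families with conserved ends and
  variable middles, and hierarchical point clouds with planted tree
  topologies, so everything is testable offline.

## CLI

```sh
# two-stage clustering of a FASTA file (internal scorers)
gtclan cluster --fasta pool.fasta --out-dir run/

# same, with imported BLAST bit scores and profile scores at the
# published thresholds
gtclan cluster --fasta pool.fasta --scorer blast-tab:hits.tsv \
    --profile-scores hhits.tsv --ssn-threshold 110 --super-threshold 160 \
    --min-family-size 150 --out-dir run/

# hierarchical tree from sequences or a distance-matrix TSV
gtclan tree --fasta pool.fasta --newick-out pool.nwk
gtclan tree --distances dist.tsv --newick-out pool.nwk

# glycan repeat units: translation, score matrix, mechanism, summary
gtclan glycan translate --glycans glycans.tsv --out tokens.tsv
gtclan glycan score     --glycans glycans.tsv --out scores.tsv
gtclan glycan mechanism --glycans glycans.tsv --out mechanism.tsv
gtclan glycan summary   --glycans glycans.tsv --out summary.tsv

# synthetic datasets
gtclan simulate proteins --seed 1 --out-prefix sim/prot
gtclan simulate glycans  --seed 1 --out-prefix sim/gly
gtclan simulate points   --seed 1 --out-prefix sim/pts
```

Glycan input is a TSV with columns `id`, `iupac_string` and optionally
`family_label`. Repeat units are written non-reducing → reducing end with the
polymerase bond marked at the boundaries, e.g. the canonical trisaccharide

```
→3)-β-D-Galp-(1→3)-α-D-Glcp-(1→4)-α-D-Glcp-(1→
```

(branches in square brackets: `…-(1→[α-L-Rhap-(1→2)]-3)-…`; `->`, `a`, `b`
are accepted for `→`, `α`, `β`). The built-in stereochemistry table covers
the common parent sugars and can be overridden with
`--stereo-table overrides.tsv` (columns `parent_sugar`, `ring_form`,
`carbon`, `config`, `orientation`).

## Layout

```
src/gtclan/
  glycan/      parser, stereochemistry table, translation, scoring, summary
  align.py     pairwise local alignment, bit scores, Scoredist-variant
  profiles.py  cluster profiles, directional comparison, BLAST/score adapters
  cluster.py   SSN → clusters → supercluster network → families
  tree.py      distance-geometry embedding, NNJ + recursive refinement
  simulate.py  seeded synthetic generators with planted ground truth
  cli.py       `gtclan` command-line front end
tests/         unit, property and acceptance tests (pytest + hypothesis)
```
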