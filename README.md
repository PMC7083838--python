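# epr — enzyme-profile relatedness

Compare genomes by the carbohydrate-active enzymes (CAZymes) they are
predicted to secrete.  Each secreted protein contributes a binary
"Function;Family" observation — the pairing of a CAZy family with an EC
number (e.g. `GH1:3.2.1.37`; the same EC in two families is two distinct
observations).  Genome profiles are compared with the Yule dissimilarity,

    d = 2 · C_TF · C_FT / (C_TT · C_FF + C_TF · C_FT)

which weighs shared presence and shared absence equally, then grouped by
complete-linkage clustering, flat threshold cuts and best-of-N
multidimensional scaling.

## What's in the box

| module | purpose |
| --- | --- |
| `epr.annot_io` | TSV dialects for annotations, secretion votes, metadata, matrices; Newick export |
| `epr.secretome` | 2-of-3 consensus secretion calling; genome quality filtering; tree-placement check |
| `epr.observations` | score accumulation (half-counts for indecisive calls), binarization, matrix assembly, singleton filtering |
| `epr.distance` | exact-rational Yule dissimilarity and the full distance matrix |
| `epr.grouping` | complete linkage (deterministic tie-break), flat clusters, seeded multi-restart MDS, adjusted-Rand congruence |
| `epr.profiling` | per-section statistics, producer types I–III, core observations, cross-section presence/absence tables |
| `epr.synthetic` | seeded generator of annotation/vote/taxonomy tables with planted hierarchical structure and ground truth |

## CLI

A full synthetic round trip:

```sh
epr simulate --out-dir data/                 # annot.tsv, calls.tsv, meta.tsv, truth/
epr build-matrix --annotations data/annot.tsv --secretion data/calls.tsv \
    --profile genus --out matrix.tsv
epr distance --matrix matrix.tsv --out dist.tsv
epr cluster  --dist dist.tsv --threshold 0.3 --newick tree.nwk --clusters clusters.tsv
epr mds      --dist dist.tsv --n-init 1000 --seed 42 --out coords.tsv
epr filter   --metadata data/meta.tsv --annotations data/annot.tsv \
    --secretion data/calls.tsv --out filter.tsv
epr profile  --matrix matrix.tsv --metadata data/meta.tsv --out table1.tsv
```

`--profile dikarya` additionally drops observations seen in only one genome.
Flat-cut presets: 0.7 (phylum), 0.3 (genus), 0.15 (within-genus); see
`epr.grouping.PRESET_THRESHOLDS`.

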