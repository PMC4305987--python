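# gofuse

Integrative gene-to-gene semantic similarity over the Gene Ontology.

No single GO semantic-similarity measure works best for every gene
pair: set-overlap measures (SimUI, TO), information-content measures
(Resnik, Schlicker, SimGIC), topology-based Wang and path-based HRSS
each capture different aspects of the annotation graph. `gofuse`
computes all of them, makes their scores comparable by within-set rank
normalization, selects per gene pair the subset of measures that agree
(the *seed measures*), and combines the seeds with a small addition
model whose weights are learned by tabu search against functional
ground truth (enzyme-class or pathway co-membership). It is aimed at
computational biologists who need a single robust similarity score per
gene pair — for functional-association networks, module detection, or
annotation-based gene prioritisation.

## Method

For a gene set *GS*, every measure *m* scores all C(|GS|, 2) pairs, the
pairs are sorted ascending per measure, and

    RankSim(g1 g2, m) = 2 · rank(g1 g2, m) / |GS|²

puts all measures on a common (0, 1) scale. On the 1-D axis of a pair's
RankSim values, the seed measure group is the largest contiguous run
with spread ≤ d′ (default 0.10) and at least *c* members (default 3);
it is labelled *high*, *low* or *mix* by where the isolated measures
fall. The final score is a type-conditional addition model

    Sim(g1, g2) = Σ_i X_i · RankSim(i) + X_α·max + X_β·min + X_γ·ave

with one non-negative, sum-to-one parameter vector X per group type.
The parameters are fitted by tabu search to maximise OptF, the mean
log fold change (LogFC) between inter-group and intra-group gene
distances over a grouping of the training genes by EC number (molecular
function) or pathway (biological process). A deliberately reversed
"fake" measure can be added to the candidate pool to check that the
integration is robust to a bad input measure.

## Worked example

Everything runs on generated data, so the example is self-contained:

```sh
gofuse simulate --n-groups 4 --genes-per-group 5 --seed 7 --out-dir demo/fx
gofuse train --obo demo/fx/ontology.obo --gaf demo/fx/annotations.gaf \
             --grouping demo/fx/groups.tsv \
             --restarts 2 --patience 10 --seed 7 --out-dir demo/run
```

prints

```
wrote fixture (40 terms) to demo/fx
OptF = 1.6027; outputs in demo/run
```

and `demo/run/logfc_report.tsv` holds one LogFC row per gene group:

```
group_id        size    logfc
1.1.1.1         5       1.8384718729052942
1.1.1.2         5       1.536111627597515
1.1.1.3         5       1.6374393140848953
1.1.1.4         5       1.398806375695319
```

OptF is the mean of the per-group LogFC values; positive values mean
genes are closer to their own group than to disjoint groups, and larger
is better. The trained weights land in `demo/run/params.json`; scoring
a new gene set with them is

```sh
gofuse score --obo demo/fx/ontology.obo --gaf demo/fx/annotations.gaf \
             --params demo/run/params.json \
             --genes g00_00,g00_01,g01_00,g01_01 --out demo/scores.tsv
gofuse network --scores demo/scores.tsv --threshold 0.5 --out demo/edges.tsv
```

which yields one `gene1 gene2 sim group_type` row per pair (similarity
is relative to the query set — ranks are computed within it) and a
thresholded functional-association edge list.

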