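# Methods

## Scope and assumptions

`wvmda` scores every miRNA–disease pair of a bipartite network by a
weighted vote of the verified associations. The method rests on the
standard assumption that functionally similar miRNAs associate with
semantically similar diseases, and on two design premises: verified
associations are more trustworthy than undetermined ones (credibility),
and only the head of each entity's similarity distribution is reliable
(filtering). The model is closed-form — no iteration, no training loop —
so every run is deterministic given its inputs.

## Pipeline

Inputs: a binary association matrix `A` (n miRNAs × m diseases, read
from a two-column edge list whose first-appearance order fixes all axis
orders), a miRNA functional-similarity matrix `FM`, and either a disease
semantic-similarity matrix `SD` or a flattened disease ontology
(child→parent term edges plus a disease→term mapping) from which `SD`
is computed.

1. Semantic similarity: per-disease ancestor DAGs, geometric term
   contributions with decay ω, similarity = shared contribution mass
   over summed semantic values. "Children of a term" always means
   children within the per-disease DAG's induced edge set, not the
   global ontology.
2. Credibility similarity on both axes of `A` (recode 1→δ, 0→base code;
   row inner products; symmetric two-row min–max rescale).
3. Integration: entrywise mean `M=(FM+CM)/2`, `D=(SD+CD)/2`, diagonal
   forced to 1.
4. Row-wise adaptive filter on `M` and `D`.
5. Weighted vote producing the score matrix `F`.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| δ (`delta`) | credibility of a verified association | 2.0 | must exceed 1; raising δ widens the raw-similarity gap between miRNA pairs sharing a verified disease and pairs sharing none, but overweights the sparse verified set if pushed far |
| `base_code` | credibility of an undetermined pair | −1.0 | −1 makes co-absence weakly informative and disagreement penalising; +1 is available via config |
| ω (`omega`) | per-level semantic decay | 0.5 | contribution of an ancestor k levels above the disease term is ω^k |
| r | filter hypothetical-position ratio | 0.1 | the cut starts at position r·k of the descending row and is refined within a 0.1-wide value bin |
| e | group-weight exponent | 1/3 | 0 disables group influence; large e lets big voter groups dominate |

All are exposed through `PipelineParams`, the CLI flags and the YAML
config.

## Numerical choices and degenerate inputs

- **Vote weight indexing.** The basic weight of every vote received by
  candidate `(mi,dj)` is `1/(N_mi+N_dj−A(mi,dj))` — indexed by the
  *candidate*. This is the form under which each non-voter candidate's
  votes total exactly 1 and each voter's total exceeds 1, which the test
  suite asserts to 1e−12; the self-vote of a voter is counted in both
  the row and the column sum. Candidates connected to no voter score 0
  instead of dividing by zero.
- **Credibility rescaling.** Row extrema include the zeroed diagonal
  (the diagonal is zeroed precisely because the huge self products would
  distort the scaling). A genuinely constant row carries no information:
  its scaling factor is defined as 0, so any entry touching it is 0.
  The rescale is invariant under positive scalar multiplication of the
  raw inner products (property-tested).
- **Filter tie-breaks.** "Closest to a bin edge" ties resolve to the
  smallest sorted position; equal similarity values sort by ascending
  matrix index; the boundary equalities of the three-branch cut rule
  (`p_f = 2p_h`, `p_l = p_h/2`) fall through to the conservative
  fallback `p = 2p_h`; `p_h = round(r·k)` uses round-half-up and both
  `p_h` and `p` clamp into `[1, k−1]`. A value sitting exactly on a bin
  edge opens its own half-open bin `[v, v+0.1)`. Filtering is row-wise
  and the output is deliberately not re-symmetrised (a `symmetrize`
  flag exists for experimentation).
- **Similarity axes.** Similarity files may contain extra labels (dropped
  with a warning) but must cover every entity of the association matrix;
  rows/columns are reordered to the association order before use.
- **AUC.** Rank-based with midrank tie handling, identical to the
  trapezoidal area under the threshold-swept ROC curve; verified exactly
  against an exhaustive pairwise oracle.

## Cross-validation protocols

Five-fold CV splits the positives (seeded) into five folds; for each
fold everything downstream of `A` — credibility similarities, integrated
and filtered matrices, voter counts, scores — is rebuilt from the
training positives only, and the held-out positives are ranked against
all pairs that are 0 in the full matrix. The split is redrawn five times
by default and fold AUCs are pooled. `FM` and `SD` derive from data
independent of the association catalogue and are therefore fixed across
folds; this is the leak-free reading, and a spy-based test asserts that
every fold model sees zeros at its masked pairs. Global LOOCV masks each
positive in turn, rebuilds the model, and ranks the masked pair against
all unverified pairs; per-trial AUCs are averaged. A `(δ, r)` grid sweep
over mean 5CV AUC is provided for calibration experiments.

## Synthetic networks

The generator plants `n_groups` latent groups shared by both axes.
In-group pairs associate with probability `boost·p0`, out-group pairs
with `p0`, where `p0` is solved so the expected density matches the
target (default 0.03, the sparsity scale of curated association
catalogues; generation fails if the implied in-group probability would
exceed 1). `FM` is 1 within groups and 0.1 across, jittered by ±`sim_noise`,
symmetrised, clipped to [0,1], unit diagonal. Disease DAGs come from a
random term tree: per-group ancestor chains of random depth meet at a
common root and each disease hangs at a random private depth (0–2 extra
terms) below its group chain, so same-group diseases share ancestors
without being identical — real ontology terms of related diseases sit at
differing depths, and exact similarity ties would otherwise collapse the
filter's smallest-position tie-break to a single survivor per row.
`permuted_null` shuffles both axes of `A` relative to the labels,
preserving degree sequences while destroying similarity alignment.

What the generator does *not* emulate: real name vocabularies, ontology
tree shapes beyond shallow random trees, degree heterogeneity beyond the
binomial variation of independent sampling, and — importantly — the
per-node association density of full-scale catalogues. Matching the
*fractional* density of a 495×383 catalogue on a 60×40 network leaves
mean node degrees near 1–2 (versus 11–14 at full scale), so the voting
signal available per candidate is far thinner than in real use: on the
default 60×40 fixture even a group-membership oracle cannot exceed
≈ 0.76–0.80 AUC (positives are i.i.d. given groups), and the pipeline
reaches ≈ 0.60–0.66 versus ≈ 0.50 for the permuted null. In denser
regimes (density 0.10–0.15, degrees ≈ 5–7) the same code reaches
0.74–0.81, which is why the protocol tests use a denser "strong-signal"
fixture. Passing tests on these fixtures demonstrate correctness of the
machinery and qualitative signal recovery, not full-scale headline
performance, which requires the real association and functional-
similarity files as external inputs.

## Known limitations

- The association edge-list format only names entities with at least one
  verified association (as curated catalogues do); isolated entities
  must be introduced through the similarity matrices they appear in.
- Filtered similarity matrices are asymmetric, so the vote received via
  a neighbour's row can differ from the reverse direction by design.
- Scores are not normalised across candidates with different voter
  counts beyond the basic fairness weight; rankings, not calibrated
  probabilities, are the intended output.
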