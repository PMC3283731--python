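# Methods

## The problem

Environmental amplicon surveys (e.g. fungal ITS and 28S/LSU rDNA clone
libraries from soil) rest on a chain of fragile steps: a multiple
alignment of length-heterogeneous, gap-rich sequences; OTU delimitation
at an identity cutoff; diversity statistics over the OTU table; and a
phylogenetic tree whose clades are compared with the OTUs. `alnscope`
implements diagnostics for each link of that chain, so that an analyst
can see — before trusting a tree or an OTU count — whether the alignment
has enough homogeneous signal to support them.

## Gap-aware entropy

Column entropy treats every cell as a unit of evidence over five
character states: the four bases plus E, a *real indel*. An unambiguous
base contributes its full weight to that base. A gap could be missing
information (any of four bases) or a true indel, so `-` contributes 1/5
to each of the five states; `N` is treated identically by default
because after the T2 treatment an `N` means exactly "a gap or an
unspecified nucleotide" (a four-state reading of `N`, spreading 1/4 over
the bases only, is available as `n_states=4` for sensitivity analysis).
Every other IUPAC code splits its weight evenly over its constituent
bases (Y → C/2 + T/2, B → C/3 + G/3 + T/3, ...). Column entropy is the
Shannon entropy of the resulting frequency vector in nats, with
non-occurring states skipped rather than contributing 0·ln 0 — which
makes the maximum attainable entropy column-dependent.

**Relative heterogeneity.** h = H/H_max compares the cumulative entropy
H = Σ H_i with the cumulative maximum. Two normalizations are offered:

- `occurring_states` (default): H_max = Σ ln k_i, where k_i counts the
  states with nonzero frequency in column i. Columns with a single state
  contribute to neither numerator nor denominator. This follows from the
  observation that skipping non-occurring states gives every column its
  own ceiling.
- `uniform5`: H_max = L·ln 5, a fixed ceiling per column.

Both are reported because the choice is a genuine modelling decision; on
a fully conserved alignment H_max = 0 and h is defined as 0 (with a
warning). H, h and the per-column profile are split into gap-free (H_f,
h_f) and gap-containing (H_g, h_g) parts; the partition H = H_f + H_g is
exact by construction. High-entropy *runs* are maximal stretches of ≥ 2
consecutive columns with H strictly above 1.5 nats, each annotated with
its mean gap frequency — in practice the long runs coincide with
gap-dominated blocks.

## Treatments

- **T2** rewrites every maximal leading/trailing `-` run as `N`,
  per record. It never changes a nucleotide, is idempotent, and turns an
  all-gap record into all-`N` (the literal reading of the rule).
- **T3** deletes a set of columns (after applying T2 if needed), given as
  1-based inclusive intervals. Deletion, not masking, so the reported
  alignment length shrinks accordingly.
- The **automatic detector** for ambiguously alignable areas flags
  columns whose windowed mean gap fraction exceeds 0.5 or windowed mean
  entropy exceeds 1.5 nats (window 5, centred moving average). Expert
  curation of alignment ambiguity is not algorithmically specified
  anywhere; these defaults are stated, overridable, and intended as a
  reproducible surrogate, not a replacement for inspection.

## OTU clustering

Percent sequence identity (PSI) between two rows is the fraction of
matching symbols over the *usable* columns — by default the global set of
columns containing no `-` in any sequence, mirroring dereplication tools
that drop gap columns up front. A pairwise-deletion mode (drop gap sites
per pair) is provided as well. Seed linkage processes sequences in input
order: each joins the first OTU whose *seed* matches at PSI ≥ cutoff
(so a cutoff of 0.95 joins at exactly 95%), else founds a new OTU.
Single linkage (connected components of the PSI ≥ cutoff graph) is the
alternative; its OTU count is provably monotone in the cutoff. A cutoff
of 1.0 is rejected: every OTU then degenerates to a (quasi-)singleton
and the distance-area parameters below become undefined.

Classes: *singleton* (one member), *quasi-singleton* (≥ 2 members,
identical over usable columns — no internal distance, so they behave
like singletons in distance space), *multiton* (the rest).

Diversity: Chao1 = S + F1²/(2F2), falling back to S + F1(F1−1)/2 when
F2 = 0 (the classic estimator, which reproduces the standard worked
example S=35, F1=24, F2=1 → 323.0); Shannon-Wiener H′ in nats; evenness
E = H′/ln S (0 for S = 1). Rarefaction is the exact hypergeometric
expectation E[S_n] = Σ_i (1 − C(N−n_i, n)/C(N, n)) computed via log-gamma,
or a seeded Monte-Carlo average; the analytic curve is the oracle the
Monte-Carlo mode is tested against (within three exact standard errors).

## Distances and saturation

Comparable sites for a pair are those where both sequences carry an
unambiguous base; gaps, `N` and ambiguity codes are excluded rather than
fractionally counted (matching the default behaviour of the common
distance programs). `complete_deletion` first restricts to the global
gap-free column set (used for tree building); `pairwise_deletion` drops
sites per pair (used for saturation profiles). Transitions are
purine↔purine or pyrimidine↔pyrimidine differences; the rest are
transversions. K2P: d = −½ ln(1−2P−Q) − ¼ ln(1−2Q). When a logarithm
argument reaches zero the distance is undefined; such pairs are recorded
in `undefined_pairs` (NaN in the matrix), never silently dropped. The
saturation profile bins per-pair (d, s, v) records (20 equal-width bins
by default) and reports the smallest bin where mean v ≥ mean s — read as
the divergence beyond which multiple hits dominate. Maximum-likelihood
estimation of per-class rate ratios is out of scope; the per-pair counts
and proportions are emitted so external tools can be applied.

## Trees

Classic NJ uses the Saitou–Nei Q criterion and reduction; BioNJ
additionally tracks variance estimates and chooses the reduction weight
λ minimizing the variance of the new distances. Both are exact on
additive matrices (the test suite verifies this against an exhaustive
least-squares scoring of *all* topologies up to 8 taxa, and against
scikit-bio's independent NJ). Ties in Q are broken by the
lexicographically smallest pair of cluster representative labels, making
the output deterministic on degenerate inputs. Negative branch estimates
are clamped to zero with the deficit shifted to the sibling edge,
preserving path lengths while keeping internal distances non-negative.

MRCA queries need a root; trees are midpoint-rooted (on a clone) by
default, with the policy overridable. The OTU internal distance is the
maximum path length from the members' MRCA to any member; it is
*undefined* for singletons (an error, not 0) and evaluates to 0 for
quasi-singletons. A tree-free fallback — half the maximum within-OTU
pairwise distance — is provided for sensitivity checks. The bootstrap
resamples columns with replacement, rebuilds the K2P matrix and tree,
and scores each original bipartition by its replicate frequency;
replicates with undefined distances are skipped but still count in the
denominator. Monophyly reports check whether each label group is exactly
the leaf set of its MRCA and average the bootstrap values of the splits
inside that clade.

## Distance areas

IODA = 100·d_int·n/N expresses an OTU's distance area (internal distance
× member count) as a percentage of the maximum possible area, which
equals the number of sequences N. RODA replaces the maximum by the
realized distance: the default `sum_internal` mode divides additionally
by Σ d_int over all included OTUs (an alternative `max_internal` mode
normalizes by the largest internal distance). The realized-distance
correction is not pinned down by a formula anywhere; `sum_internal` is
the default because it yields the self-normalizing behaviour expected of
a "realized" share (a single included OTU gets RODA = 100·n/N) and
spans the plausible magnitude range on realistic inputs; both modes are
explicit reconstructions and configurable. Singletons and
quasi-singletons are listed but excluded from all areas. Plot
coordinates put d_int on x and RODA (or IODA) on y with boundary lines
at n = 2 and n = N; since 2 ≤ n ≤ N, every included point lies between
the lines, and two-member OTUs lie exactly on the minimum line. The
cutoff sweep clusters at an increasing cutoff ladder and links each OTU
to the parent containing its seed at the previous cutoff.

## Synthetic fixtures

The generator emulates a cloned-amplicon survey: by default 120
sequences (three samples of 40) in a ~1 kb alignment of conserved,
variable and gap-rich blocks (per-cell i.i.d. gaps within gap-rich
blocks), leading/trailing overhangs up to 25 columns, sparse IUPAC
ambiguities (rate 0.001), and 10 planted clusters at 1% within- and 20%
between-cluster divergence — magnitudes chosen to mirror congeneric
variation versus family-level divergence in rDNA amplicon sets.
Substitutions follow a K2P scheme with ts:tv = 2, the same model used
downstream, so divergences are interpretable on the K2P scale.

Divergence semantics are deliberately *exact-count*: `within_divergence`
ε is the nominal pairwise divergence between two cluster members, and
each member receives exactly ε/2·L_mutable substitutions at distinct
sites from its ancestor; likewise each ancestor receives δ/2·L_mutable
from the root. Coincident substitutions can only lower realized
divergence, so within-cluster PSI ≥ 1−ε holds deterministically and
identity clustering at any cutoff c with ε ≤ 1−c ≪ δ recovers the
planted partition by construction — the recovery tests exercise this
guarantee over seeds rather than hoping binomial noise stays inside the
band. The flip side: single-draw exact counts create no multiple hits
within a lineage, so these fixtures never show substitution saturation.
The separate `divergence_ladder` generator (stepwise mutation with sites
drawn *with* replacement) provides genuine multiple-hit accumulation;
with ts:tv = 2 its transversion counts overtake transitions near the
closed-form K2P crossover of d ≈ 1.37, which the tests check as a band.

What the fixtures do not emulate: realistic indel evolution (gaps are
i.i.d., not phylogenetically structured), chimeras, sequencing error,
rate variation across variable sites, and abundance skew (cluster sizes
are as even as possible). Passing tests therefore demonstrate the
correctness and calibration of the statistics, not their behaviour on
the messier structure of real clone libraries.

`resampling_profile` quantifies pure sampling noise: drawing n items
without replacement from a large finite pool of labelled classes and
reporting per-class mean percentages and across-replicate SDs (checked
against the exact hypergeometric variance). It answers how faithfully a
small clone library (e.g. 120 of 120 000) can reflect community
composition at best.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; the CLI threads one `--seed` through every stage.
- Frequencies use double precision; the entropy oracle in the tests uses
  exact fractions, and agreement is required to 1e-9.
- Medians over even column counts are midpoints of the central pair.
- Column coordinates in all I/O are 1-based inclusive; `U` maps to `T`;
  NEXUS `?`/`.` map to `N`/`-`; everything is uppercased on ingestion.
- Problem sizes in the test suite and acceptance script (30–120
  sequences, 0.6–1 kb, 100-seed sweeps, ≤ 8-taxon exhaustive tree
  oracles, 300-replicate Monte-Carlo) are chosen so the full suite runs
  in well under a minute while keeping every statistical check
  non-trivial.
- The NJ implementation is O(n³) pure numpy; it is comfortable to a few
  hundred taxa but not intended for thousands.
- Quasi-singleton detection compares sequences over usable columns only;
  two sequences differing solely inside gap-containing columns count as
  identical, consistent with the identity denominator used for
  clustering.
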