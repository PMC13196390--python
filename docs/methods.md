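# Methods

This note documents the models, parameters and design choices behind
`pepwire`, in the order the pipeline runs them.

## Study design and data model

The design is four conditions — an untreated control plus three kinase
inhibitors (a BCR-ABL inhibitor, an SFK-family inhibitor and a JNK
inhibitor) — in biological triplicate. All four omic layers share one
container, a features × samples grid of log2 intensities with `NaN` as the
explicit missing marker (an empty cell or the literal `NA` on disk; no
numeric sentinel, which could collide with real intensities). Residue
positions are 1-based throughout, matching the convention of site labels
like S727.

The causal network is a signed, typed, directed multigraph. Kinase families
are single nodes carrying a `family_members` list; wherever a concrete
kinase is needed (mechanism path search, inhibitor maps) the family is
expanded to its members plus itself. Phosphorylation edges may carry a
(residue, position) site on their target; transcriptional edges must leave a
TF node and phosphorylation edges a kinase node — both are validated on
load.

## Differential stage

1. **Log2 transform** of raw intensities (strictly positive; violations name
   the offending feature).
2. **Detection filter**: a feature is kept iff it is observed in at least
   `detection_min = 2` of 3 replicates of at least one condition.
3. **MinProb imputation** of left-censored missingness: each missing cell in
   sample *s* is drawn from `Normal(μ_s, σ_s)` with `μ_s` the
   `imputation_q = 0.01` quantile of the sample's observed values and
   `σ_s = 0.3 ×` the observed standard deviation. The method name specifies
   the low-quantile mean; the width factor 0.3 is this package's explicit
   parameterization (narrow enough that imputed values stay near the
   detection floor, wide enough to avoid zero-variance artifacts). Observed
   cells are never touched; draws are deterministic under the stage seed. A
   sample with fewer than two observed values is an error (its quantile is
   undefined).
4. **Testing**: per treatment, an equal-variance two-sample Student *t* test
   against the control (Welch available behind `welch = true`), two-sided,
   with Benjamini–Hochberg adjustment across the features of one
   (layer, treatment) family — the family that matches per-treatment volcano
   plots. Significance requires `|log2FC| > 0.5` *and* adjusted `p < 0.05`.
   Degenerate zero-pooled-variance features (noise-free fixtures) get
   `p = 0` when the means differ and `p = 1` otherwise, with a logged
   warning.

## Proximity screen

Path counting uses **simple directed paths** (node sequences; parallel edges
do not multiply counts) of length 1..`proximity_max_path_len = 4` that stop
at the first target-set member reached — a peptide of the target pathway
should not also be counted as a waypoint. A length cap is mandatory for
tractability on dense signaling networks; 4 steps already spans
kinase → kinase → TF → target chains. The shortest distance is capped the
same way, so `path_count ≥ 1 ⇔ finite distance`. Z scores standardize the
finite distances with the sample standard deviation (ddof = 1, which
reproduces the natural hand calculation on {1,2,3} → ∓1); candidate
selection (`Z < 0` ∧ druggable) is invariant to that choice. Ordering is
deterministic: path count descending, then node id. Edge signs are ignored
here — the screen asks only for connectivity in either direction of effect.

## Mechanism assignment

A drug enters the network as activity −1 at each inhibited kinase (families
expanded). The predicted sign of any downstream observation is
`−1 × ∏ edge signs` along a directed path; the empty path is the inhibited
kinase itself.

* **M1 (direct peptide phosphorylation)**: for each significant
  phospho-HLA peptide, the annotated upstream kinases of its site are
  sought within `m1_max_steps = 2` of an inhibited kinase; the predicted
  peptide sign is the propagated phospho sign at the site. The supporting
  check reads the upstream kinase's activity from its annotated
  activation-site phosphosites (inhibitory sites flip the sign; several
  sites vote by majority, ties abstain).
* **M2 (source-protein stability)**: for significant HLA peptides whose
  source protein carries a stability-annotated site, the site's phospho sign
  is propagated as in M1 (cap `m2_max_steps = 2`); the stability change is
  `site sign × (+1 stabilizing / −1 destabilizing)`; the protein follows
  stability and the peptide opposes it (a stabler protein is degraded less,
  so peptide supply falls). Supporting checks: the site's phosphosite, the
  protein's abundance, the kinase's activity.
* **M3 (transcriptional regulation)**: every TF reachable within
  `m3_max_steps = 3` ("directly or indirectly") of an inhibited kinase gets
  an activity sign — the propagated phospho sign at its activity site,
  flipped for inhibitory sites; a TF without an annotated activity site uses
  the propagated sign directly and is flagged. Each signed TF→target
  relation predicts the target protein and its peptides
  (`activity × regulation sign`). Supporting checks: the TF site phosphosite
  and the target-protein abundance.

Step caps for M1 and M3 are this package's choices (M1 mirrors the explicit
two-step stability cap; M3 is one step longer to honor "indirect"
regulation); all are config-exposed. When several shortest paths or parallel
edges exist, **all** (path, sign) candidates are evaluated; the assignment
reports an agreeing path if any exists plus the counts of agreeing and
disagreeing candidates. Mechanisms are not mutually exclusive — one peptide
may receive M1, M2 and M3 explanations.

**Consistency verdicts.** Non-significant observations contribute no sign.
`lenient` (default) requires the peptide sign to match the prediction and
any *measured, significant* supporting sign to agree — intermediate
measurements are often unavailable in real data, and demanding them would
discard valid explanations. `strict` additionally requires every supporting
layer to be measured and agreeing.

Recovery against planted truth scores a (peptide, treatment, mechanism)
triple as a true positive iff it was planted and the assignment is
consistent. Empty predictions give precision 1.0 by convention, flagged.

## Antigen sets

Binder = strong ∪ weak calls (restrictable to strong). TAA = binder ∧
cohort presence ≥ 1 sample ∧ benign presence = 0; the cohort floor is
config-exposed. Putative TAA = TAA ∧ significant *up* under ≥ 1 treatment.
Peptide identity across datasets is the exact case-normalized amino-acid
string. All set outputs are order-invariant and reproducible by plain set
algebra.

## Synthetic study generator

The generator is the package's test bed: it emulates the study *structure*,
not any particular measured dataset.

* **Network**: per treatment and mechanism, `n_motifs_per_mechanism = 10`
  independent motifs are rooted at that treatment's inhibited kinase (the
  SFK-family treatment roots at a member, exercising family expansion).
  Every planted feature's effect sign is the sign-propagation product of its
  motif, so mechanism consistency holds by construction and the generator's
  bookkeeping doubles as a cross-module oracle for the propagation code.
  Druggable kinases are wired into three APPM target nodes at distance 1
  with a graded periphery behind them, so the proximity screen recovers
  exactly the planted inhibitor targets; 200 background nodes form a
  disconnected random subgraph.
* **Intensities**: feature baselines ~ `Normal(25, 2)` log2 units;
  replicates add `Normal(0, 0.5)`; planted effects shift the treated mean
  only (homoscedastic noise keeps the Student-*t* assumption exact).
  Background layers are desk-scale reductions of real layer sizes
  (2,000 peptides, 30 phospho-HLA peptides, 800 proteins, 1,500
  phosphosites). Twenty percent of background features per treatment are
  drug-modulated with `|log2FC| ~ Uniform(2, 10)` — matching the observed
  situation in which a kinase inhibitor moves a large fraction of the
  peptidome with fold changes from 4× up to three orders of magnitude.
  Without this modulated background the BH step-up cannot engage at df = 4
  and no sparse-mixture effect is recoverable. Mechanism-motif features
  carry `|log2FC| = 4` (16-fold, mid-range of strong drug responses).
* **Missingness** is left-censored: each cell drops out with probability
  `0.3 × sigmoid((midpoint − x) / 1.0)` with the midpoint at the 5th
  baseline percentile — the intensity-dependent mechanism MinProb presumes.
  The true missingness process of any instrument is unknown; a logistic
  model controls both the rate and its intensity dependence with two
  numbers.
* **Cohort structure**: 25 planted TAAs (binders, ≥ 1 of 21 cohort samples,
  0 of 30 benign samples; about half chosen among peptides planted to go
  up, so the putative-TAA filter has recoverable targets), 50 decoy binders
  present in both cohorts, everything else absent from the disease cohort —
  making the planted TAA set exactly recoverable by set algebra. Five
  cancer-testis antigen proteins are planted with roughly half their
  peptides also present in benign tissue.
* One peptide maps to one source protein by default; multi-mapping is
  exercised by dedicated test fixtures.

**What passing tests do and do not show.** The generator's noise is
homoscedastic Gaussian with independent features, its network motifs are
clean and disjoint, and its presence lists are Bernoulli draws; real data
have correlated features, batch structure, shared and noisy annotations, and
imperfect binder calls. Recovery scores on synthetic data validate the
*logic* of the pipeline (sign algebra, set logic, calibration of the tests
under their assumptions), not performance on any real study.

## Reproducibility and numerics

Every stage draws from a child seed derived by CRC-32 from the global seed
and a stage label, so stages can be rerun in isolation; all child seeds stay
below 2³¹. Matrices are written with `%.17g` (exact IEEE round-trip) and
read with round-trip float parsing, making the full pipeline byte-identical
across reruns — verified by digest comparison. Problem sizes in the test
suite and acceptance script (2,000-feature null matrices over 20 seeds,
1,000-feature power runs, 20 default-noise recovery seeds, 100 oracle
graphs, 1,000 imputation draws) were chosen to keep Monte-Carlo error small
relative to the frozen thresholds while the whole suite runs in well under a
minute on one core.

## Frozen statistical thresholds

* FDR calibration: under a global null each BH family's false-discovery
  proportion is Bernoulli(≤ 0.05); over 20 seeds × 3 families the mean must
  stay below 0.05 + 2·√(0.05·0.95/60) ≈ 0.106, frozen at 0.11.
* Power: with |log2FC| = 2, sd 0.5 and n = 3 + 3 the noncentral-*t*
  (ncp = 4.899, df = 4) two-sided power at 0.05 is 0.948 on a dense
  alternative; the floor is the oracle minus five points, 0.898.
* Mechanism recovery: exact (precision = recall = 1) at zero noise; mean
  overall F1 ≥ 0.9 over 20 default-noise seeds.

## Known limitations

* The network is an input; no causal discovery or kinase-substrate inference
  is performed, and activity is read from annotated activation sites only
  (no substrate-enrichment statistics).
* Walk-vs-path semantics and the length cap of the proximity screen are
  choices; absolute path counts depend on them, the Z-ranking much less so.
* Binder calls and immunogenicity scores are consumed as annotations, never
  recomputed.
* File-mode runs assume the default four-condition design; custom designs
  are available through the library API.
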