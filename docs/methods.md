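# Methods

This note documents the models, parameter choices, and numerical decisions
behind `hybridtrace`, and what the simulation-based tests do and do not
establish about real data.

## Scenario and model

The package targets populations of 2–4 coexisting bacterial species that
diverged in isolation and later began exchanging core-gene sequence by
homologous recombination, sampled by single-cell genomics.  The working
units are per-orthogroup multiple-sequence alignments over cells
(0-based, half-open coordinates throughout), a cell table (sample, species,
completeness), and — in simulations — a truth table recording the ancestry
of every (cell, gene, interval).

### Forward simulator

Each gene is built in four layers:

1. **Ancestral sequence.**  Codons are drawn with fourfold-degenerate (4D)
   prefixes, so every third position is synonymous in the ancestor.  This
   maximizes the density of scorable synonymous sites and keeps synonymous
   bookkeeping exact; it overstates the 4D density of real genes (~1/3 of
   sites here vs ~1/5–1/4 in real coding sequence), which affects only the
   *number* of scorable sites, not any per-site statistic.
2. **Between-species divergence.**  Substitutions are placed independently
   per species on a star-like species tree.  Two rates are used: an
   all-site target `between_div` (default 0.15, the typical genome-wide
   nucleotide divergence between closely related but distinct species) and
   a higher 4D-site target `between_div_syn` (default 0.30).  The split
   reflects purifying selection: synonymous sites diverge faster than the
   genome-wide average, and the divergence-trough cutoff d_trough = 0.2
   operates on the synonymous scale, *between* the typical synonymous
   divergence and the within-species level.  Per-branch substitution
   probabilities are solved from the two-branch collision equation
   d = 2p − (4/3)p², so realized pairwise divergences hit the targets
   despite coincident hits.
3. **Within-species diversity.**  A Kingman coalescent per (species, gene)
   with infinite-alleles-style mutations restricted to that species' 4D
   sites, at per-site θ = `within_div` (default 0.04, a typical synonymous
   diversity for a diverse free-living species).  E[π_S] = θ by the standard
   coalescent argument.  A configurable fraction of the first species'
   genes (`backbone_frac`) uses θ scaled by `backbone_ratio` (default 0.01),
   creating the two-orders-of-magnitude backbone/hybrid diversity contrast.
4. **Planted events.**  Whole-gene transfers (per-gene Bernoulli), sub-gene
   transfers (per-gene Poisson; interval length uniform on 30–300 bp,
   matching the short donor-segment scale that SNP blocks detect), and
   hard/soft sweeps (all recipient cells descend from 1 or ≥2 donor
   founder alleles).  Transfer carriers copy one donor allele exactly;
   diversification of carriers after transfer is represented only through
   the soft-sweep multi-founder mechanism, not by post-transfer mutation
   (a deliberate simplification — transfers here are recent on the
   coalescent time scale).

SAG missingness is gene-wise Bernoulli: each gene is observed in each cell
with probability equal to the cell's completeness, drawn from a scaled Beta
with mean 0.3 on [0.05, 0.95].  Sequencing error is off by default
(`error_rate` adds uniform base miscalls for robustness experiments).
Everything is deterministic given the seed, to the byte in FASTA output.

**What the simulator does not emulate:** gapped alignments and indels,
partial gene recovery (missingness is all-or-nothing per gene), paralogy
and orthogroup construction error, contig structure (so contig-level
hybrid-cell exclusion is out of reach), GC/codon bias, and rate variation
across sites.  Passing recovery tests therefore demonstrate correctness of
the inference chain under clean alignments with realistic missingness, not
robustness to assembly artifacts.

### Neutral-coalescent linkage anchor

`simulate_neutral_ld` draws independent non-recombining Kingman genealogies,
adds infinite-sites Poisson mutations, pools all within-locus segregating
site pairs, and returns σ²d as a ratio of sums.  The asexual drift value is
5/11 ≈ 0.4545; at sample size 30 the statistic carries a small positive
finite-sample offset (≈ +0.02–0.03, shrinking with sample size: ≈ 0.46 at
n = 100), comfortably inside the ±0.05 acceptance band at 5000 loci.  The
engine is cross-checked in the test suite against an independent coalescent
simulator (msprime) at matched sample size.

## Inference chain: parameters and defaults

| Parameter | Default | Role |
|---|---|---|
| `alpha_core` | 1e-3 | lower binomial tail below which a gene's occupancy is inconsistent with single-copy presence |
| `d_split` | 0.075 | whole-cell species assignment: nearest reference must be closer than this |
| `d_c` | 0.075 | per-gene cluster cut; also the intra-cluster max and inter-cluster min acceptance scale |
| `min_mac` | 2 | minor-allele count for a SNP column (singletons are uninformative for linkage) |
| `min_joint` | 10 | cells jointly covered required per site pair / block extension / block pair |
| `f_cut` | 0.05 | backbone iff fraction of polymorphic 4D sites < f_cut (strict) |
| `d_trough` | 0.2 | trough iff mean cross-species synonymous divergence below this |
| `soft_factor` | 10 | soft sweep iff hybrid-allele π_S exceeds this multiple of the backbone per-site rate |
| `min_snps`, `min_block_cells` | 3, 3 | conservative block emission minima |
| `max_gap_bp` | 300 | maximum separation between adjacent block SNPs |
| `mosaic_frac` | 0.8 | "one very large cluster" threshold in the mosaic rule |

Numerical and procedural choices that were genuinely open:

* **σ²d estimator.**  Ratio of expectations (sums pooled before the ratio)
  at every level — per bin, genome-wide, and in the neutral anchor — since
  the 5/11 value and the decay-model fit are defined for that form.  Pairs
  monomorphic among their jointly covered cells contribute zero to both
  sums and so cannot bias the ratio; an all-monomorphic input is an error.
* **Core-gene calling.**  One-parameter binomial with the mean completeness
  rather than the exact Poisson–binomial over heterogeneous cells; at
  n ≈ 100–300 cells the approximation error is far below the 1e-3 tail
  threshold.  The rule is monotone in the presence count by construction.
* **Clustering.**  Average-linkage agglomeration on pairwise divergences
  (pairwise-complete over non-missing sites; incomparable pairs get
  divergence 1.0), cut at d_c.  Accepted clusters must be internally tight
  (max intra < d_c) and separated (min inter ≥ d_c); when two accepted
  clusters violate separation the smaller is demoted to unassigned.
  Cluster output is invariant to input sequence order.
* **Locus classes.**  With 2–4 accepted, well-separated clusters the locus
  is simple-hybrid if any cluster mixes species (or a species owns a
  surplus cluster — an unknown-donor signature) and non-hybrid if all are
  pure with sizes within ±3√(expected) of the completeness-weighted
  expectations (binomial sampling noise).  Mosaic requires the *absence* of
  distinct species structure: zero or one accepted cluster (including the
  dominant-mixed-cluster case) or ≥5 fragments.  Distinct-cluster structure
  takes precedence because whole-gene transfers legitimately reach
  frequencies near 100%, where the mixed host cluster dominates the
  alignment yet the locus is still a simple hybrid.
* **Transfer direction.**  The majority (>50%) species of a cluster is the
  donor for its minority members; exact ties drop the event with a log
  message.  Clusters containing the single-cell third species donate with
  direction flagged unresolved; surplus clusters map to the unknown donor X.
* **4D sites.**  Called per species from the majority-rule species
  consensus (ties alphabetical, flagged); columns missing in >50% of cells
  are excluded.  Cross-species divergence profiles use sites 4D in *both*
  species.  π_S is pairwise-complete per sequence pair — a global
  complete-case reduction would discard most SAG data.
* **Poisson goodness.**  Count classes pooled from the right until the tail
  expectation reaches 5; dof = classes − 2 (one fitted parameter).
* **Block search.**  Greedy left-to-right extension of perfect-linkage
  runs; a run breaks when the next SNP (within `max_gap_bp`) fails the
  exact two-haplotype partition test over ≥ `min_joint` jointly covered
  cells.  Runs are maximal and disjoint; cells are assigned to a haplotype
  only while their covered columns agree with exactly one side.  Emitted
  blocks are verified in tests by brute-force haplotype enumeration.
* **Unlinked controls.**  Per-site (or per-block) permutation of observed
  alleles across covered cells, preserving allele frequencies and the
  missingness pattern exactly; this is the correct finite-sample baseline
  because σ²d and r² do not vanish under independence in finite samples.

## Benchmark problem sizes

The recovery benchmarks are sized so a full run of the suite plus the
acceptance script completes in a few minutes on one CPU, while keeping
every estimate's Monte-Carlo error well inside its acceptance band:

* classification recovery: 100 genes × (100+100) cells at completeness 0.3
  — about 30 planted transfers, and enough cells that a frequency-0.1
  transfer is expected to leave ≥3 observed carriers;
* trough recovery: 45 genes of 900 bp (300 4D sites each), so the per-gene
  divergence SD (~0.03) puts non-swept genes >3 SD above d_trough;
* sweep modes: 100 sweep loci (50 hard, 50 soft with 5 founders);
* SNP blocks: 40 genes × 50 recipient cells, fully observed, with a
  backbone-level recipient (θ ratio 0.01): blocks are the footprint of
  donor segments against a low-diversity background, and recipient-side
  segregating sites would otherwise break perfect-linkage runs by
  construction — this matches where block detection is scientifically
  applicable;
* neutral anchor: 5000 loci, sample size 30, per-locus θ = 3.

## Known limitations

* The unknown-donor (X) call cannot distinguish an extinct/unsampled donor
  from a deep-coalescing resident lineage.
* Direction of transfers involving a single-cell species is unresolvable in
  principle; events are emitted flagged rather than guessed.
* The decay-model fit assumes the infinite-sample form; at small sample
  sizes the plateau sits above 5/11 and ρ̂ absorbs part of the offset.
* Block detection requires the two-haplotype regime; it loses power inside
  high-diversity (quasisexual) species where within-species polymorphism
  interleaves with donor segments, and the reported fraction of SNPs inside
  blocks should be used to calibrate thresholds before cross-dataset
  comparisons.
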