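# Methods

## The measurement model

A co-fractionation profiling experiment quantifies each protein's XIC-based
intensity across ordered chromatographic fractions. On a size-exclusion
column, a single native species produces an approximately Gaussian elution
band, so a protein distributed over several oligomeric states produces a
profile that is a sum of Gaussians:

    I(f) = Σ_k A_k · exp(−(f − μ_k)² / (2 σ_k²)),   k = 1..K, K ≤ 4

with `f` the 1-based fraction index (fractions are equal-volume, so fraction
number and elution volume are affine-equivalent), `μ_k` a continuous center
on the same axis, `σ_k` the band width in fractions and `A_k` the amplitude
in intensity units. The cap of four components reflects what the column can
genuinely resolve over ~24 fractions.

Zero intensities are treated as signal below the detection limit, not as
missing data: absence of an XIC is informative about where a protein does
not elute.

## Deconvolution

For each eligible profile (detected in ≥ 3 fractions, at least two
adjacent) the mixture is fitted for K = 1..4 by bounded nonlinear least
squares (SciPy trust-region reflective, analytic Jacobian). Intensities are
rescaled to unit maximum inside the optimizer — raw XIC scales span orders
of magnitude and otherwise stall convergence — and amplitudes are rescaled
back afterwards.

- **Initialization.** Candidate centers are the local maxima of a 3-point
  moving-average smooth, ranked by raw height; σ starts at 1.5 fractions.
- **Bounds.** μ ∈ [first fraction − 1, last fraction + 1]; σ ∈ [0.5, 5]
  fractions; A ∈ (0, 2 × max intensity]. These forbid spike and plateau
  degeneracies.
- **Acceptance rules, applied post-fit.** Peaks below 20% of the dominant
  amplitude are pruned and the model refitted at the reduced K; candidate
  models whose centers are closer than 4 fractions are discarded outright.
  Keeping the optimizer unconstrained and filtering afterwards is simpler
  and numerically better-behaved than hard constraints, and close-peak
  candidates lose to the corresponding single-peak model anyway.
- **Model selection.** The surviving candidate with the lowest
  `BIC = n·ln(RSS/n) + 3K·ln(n)` wins (n fraction points, 3 parameters per
  peak). A perfect fit substitutes an RSS floor of 1e−12 to keep the score
  finite. The exact BIC variant used by earlier co-fractionation tools is
  not published; this is the standard least-squares form and is frozen in
  `bic_score` with a closed-form oracle test.
- **Fallback.** If no candidate survives at any K, the profile's global
  maximum becomes a single integer-center peak (ties to the earlier
  fraction, logged). Ineligible profiles are excluded entirely rather than
  rescued by the fallback. Fitting is deterministic; there are no random
  restarts.

An internal consistency diagnostic mirrors practice: across simulated
profiles, the dominant fitted peak should sit within one fraction of the
profile's global maximum ≥ 95% of the time. The comparison rounds the
continuous fitted center to the nearest fraction, since the global maximum
only exists on the integer grid.

## Reproducibility and labels

Peaks from the two biological replicates are matched one-to-one, greedily
by smallest center shift, accepting pairs with shift ≤ 2 fractions
(inclusive; the threshold and its inclusivity are configurable because the
two-fraction rule is quoted both inclusively and exclusively in the
literature). Under the package's own invariants — within-replicate
separation ≥ 4 fractions, tolerance 2 — each peak has at most one possible
partner, so the greedy matching coincides with the exhaustive optimal
assignment; a test verifies this against a brute-force oracle on all ≤ 4×4
peak sets. Unmatched peaks are dropped and logged.

Matched resolved peaks get per-replicate apparent masses and a consensus
mass equal to their geometric mean (masses are log-linear in elution
position, so averaging belongs on the log scale). Labels P1, P2, …
follow decreasing apparent mass; unresolved void peaks elute earliest and
lead the order but carry no mass.

## Calibration and the void

`log10(mass_kda)` is regressed on peak fraction by OLS over the standards
(29–669 kDa). Masses computed outside the standards' range are flagged as
extrapolations but still reported. A peak is *resolved* only when its
center is at least one full fraction past the void fraction
(`center ≥ void + 1`, inclusive); sucrose gradients have no void and
resolve everything. The void peak itself is never a calibration point.
Superdex and Superose columns get independent calibrations; a per-column
`upper_quotable_kda` bound (defaults 900 kDa and 5 MDa) marks which
column's mass is quotable for very large species.

## Oligomer calls

`R_app = M_app / M_mono` with the annotated monomer mass. States:
degraded < 0.5 ≤ monomer < 2 ≤ small complex < 10 ≤ large complex (all
boundaries inclusive on the right-hand class). The state class uses the
geometric-mean R_app; the complex prediction deliberately uses the
per-replicate values (reproducible peak and R_app ≥ 2 in at least one
replicate), so a protein can be a "monomer" by consensus yet flagged as a
putative complex by one replicate. Proteins whose only peaks are in the
void are reported as `unresolved`, outside the four classes.

## Membrane filtering and dual localization

Cholate-detected proteins never seen in the cytosol are accepted as
membrane-associated outright. Proteins with a cytosolic pool must show a
reproducible sucrose velocity-gradient peak strictly beyond fraction 8
("beyond" read as > 8 on the dominant — highest-amplitude — reproducible
peak; the boundary and the dominant-peak choice are configurable, and
alternate peaks are visible in the peak tables). Anything else is flagged a
cytosolic contaminant. Cytosolic apparent masses come from an external
soluble-fraction table and are never recomputed here. In the
dual-localization screen, cytosol/membrane mass ratios > 2 or < 0.5 flag an
oligomerization shift; cytosolic masses ≥ 450 kDa are excluded from the
screen because complexes that large can sediment deep into the gradient on
their own.

## CoIP evidence

Interactor acceptance is presence/absence over a 3 + 3 replicate design:
≥ 2 peptides, and either detection in ≥ 2 of 3 antibody replicates with no
control signal, or in all 3 antibody replicates with at most one control.
Intensities beyond presence are not compared.

## Reference complexes

Ortholog maps from any number of external predictors are consumed as plain
two-column tables; the union of sources is used and, where sources
disagree, the first source listed wins (multiplicity is logged). Complexes
whose projected target subunit sets are identical collapse to one record
(first species kept, others as aliases); subset relations are not
collapsed. M_calc sums each subunit's monomer mass once — unit
stoichiometry is a known simplification, biased low for complexes with
multi-copy subunits. The target-species M_calc is only defined at 100%
ortholog coverage.

## Analytics

The replicate diagnostic correlates, over shared proteins, every fraction
of replicate 1 with every fraction of replicate 2 (Pearson); a reproducible
separation puts row maxima on or adjacent to the diagonal. Clustering
operates on Gaussian-reconstructed profiles (accepted peaks evaluated on
the fraction grid), unit-max normalized, with distance 1 − Pearson and
average linkage; both the distance and linkage are package choices exposed
in the API, since only the method family is standard. Leaf order is
deterministic and row-permutation invariant; the dendrogram is exported as
Newick.

## The synthetic-data generator

`SimulationConfig` defaults define the simulated study:

| parameter | default | meaning |
|---|---|---|
| `sec_fractions` / `sucrose_fractions` | 24 / 25 | fraction counts per separation |
| `void_fraction` | 2 | collection starts one fraction before the void |
| `peak_count_probs` | 0.82/0.14/0.03/0.01 | 1–4 peaks per protein, matching the observed predominance of single peaks |
| `state_probs`, `state_rapp` | 0.05/0.45/0.30/0.20 at R_app 0.3/1/4/12 | oligomer-state mixture and class-representative ratios |
| `sigma_range` | 1–2.5 fractions | chromatographic band widths |
| `secondary_height_range` | 0.4–1.0 | secondary-peak relative amplitudes |
| `jitter_sd` / `jitter_max` | 0.5 / 2 fractions | per-replicate center jitter (truncated normal) |
| `noise_cv` | 0.20 | multiplicative log-normal intensity noise |
| `additive_floor_rel` | 0.01 | baseline noise relative to the profile maximum |
| `dropout_prob` / `dropout_max_rel` | 0.05 / 0.25 | detection loss; only fractions below 25% of the maximum can drop out, because a strong XIC does not vanish |
| `void_trapped_frac` | 0.10 | aggregates confined to the void |
| `contaminant_frac` | 0.30 | cytosolic contaminants (sucrose peaks in fractions 2–7.5, 10% with low-level deep bleed-through) |
| `dual_localized_frac` / `dual_shift_prob` | 0.30 / 0.25 | membrane proteins with a cytosolic pool; fraction with a 4-fold inter-compartment shift |
| `monomer_mass_range_kda` | 15–200 (log-uniform) | annotated monomer masses |

The primary peak center is placed exactly where the calibration law puts
`M_app = R_app × M_mono`, and the standards are noiseless points on that
law, so truth ratios round-trip exactly through the calibration module.
Monomer masses are resampled until the implied center is resolvable.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide sharing, ion suppression, correlated noise between adjacent
fractions, asymmetric (tailing) peak shapes, glycosylation- or
shape-driven mobility artifacts, and genuinely shared peaks between
co-complex proteins. Passing recovery tests therefore demonstrates that
the inference machinery is correct under its own model assumptions — not
that real chromatography is this clean; on real data the reproducibility
filter and the R_app threshold absorb part of that gap.

## Problem sizes and numerical choices

Simulated benchmarks use 500 proteins per study (the package's standard
benchmark size; recovery statistics are stable well below that). Peak
recovery is scored against per-replicate jittered truth with a one-fraction
matching tolerance and a 0.5-fraction center-accuracy criterion.
Degenerate inputs are handled explicitly: all-zero profiles are
"ineligible"; tied global maxima take the earlier fraction; zero RSS uses
the BIC floor; all-zero matrix rows are dropped before normalization;
zero-variance fractions yield NaN correlations rather than errors.

## Known limitations

- Unit stoichiometry in M_calc underestimates complexes with repeated
  subunits.
- Globular-shape assumption: elongated or heavily glycosylated proteins
  inflate M_app, hence R_app, and can cross the complex threshold without
  a true interaction.
- The R_app ≥ 2 threshold misses complexes whose partner is much smaller
  than the protein itself.
- Cross-column (Superdex vs Superose) peak matching and > 2-replicate
  consensus are out of scope.
- Only exact duplicate complexes are merged during deduplication; near-
  identical complexes differing by one subunit remain separate records.
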