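# Methods

This note documents the models, conventions and numerical choices behind
`nfixdiv`, and what the synthetic-data validation does and does not show.

## Diversity metrics

All metrics operate on a rooted tree with branch lengths in millions of
years (My) and a species set drawn from its tips.

**Faith's PD** is the summed branch length of the minimal subtree
connecting the set. We use the *root-inclusive* convention: the subtree
includes the path down to the root, so a single species contributes its
full root-to-tip lineage length. The main alternative — crown-based PD,
which stops at the set's own MRCA — is available via `rooted=False` in
`faith_pd`; the two differ by the root-to-crown path length. Root-inclusive
is the default because it is what the standard community-phylogenetics
toolchain computes and it keeps PD monotone under set inclusion even for
singletons.

**MPD** is the unweighted mean of patristic distances over unordered
pairs; **MNTD** the mean over members of the distance to the nearest other
member. Both need at least two species; the pipeline applies the
convention MPD = MNTD = 0 for single-fixer surveys so those plots can stay
in the distance-metric analyses, and Faith's PD of an *empty* fixer set is
taken as 0 so that a plot losing its last fixer still has a defined PD
change. These conventions live in the pipeline layer; the metric
primitives themselves raise on degenerate sets rather than guessing.

## Grafting species onto the reference tree

Resurvey data always contain species missing from any reference
phylogeny. A missing species with congeners in the tree is added at the
genus level: if the genus has two or more tips, the new tip joins the
genus crown node as a polytomy; if exactly one, the congener's pendant
branch is split at its midpoint and the pair becomes a cherry. Species
with no congeners fall back to the same rules at the family level, and
species whose genus and family are both absent raise an error listing
them so the caller can decide to drop them. The pendant length is chosen
so the new tip's depth equals the mean depth of its anchor group, which
preserves ultrametricity exactly on dated trees. All anchors are resolved
on the original tree, so the result does not depend on grafting order.
The crown-polytomy choice is one of several defensible placements (a
stem-split is the other common one); it is deterministic and flagged here
as the natural target for a sensitivity analysis.

## Environmental predictors

Each site carries annual series of N deposition rate (g N m⁻² yr⁻¹),
mean temperature (°C), precipitation and potential evapotranspiration
(mm). Three predictors summarize a site's trajectory between its two
survey years:

- **Cumulative N deposition**: the annual deposition amounts summed over
  the half-open interval (baseline, resurvey] — deposition accrued after
  the baseline census. The half-open convention avoids double-counting
  the baseline year and makes the sum additive over concatenated
  intervals; a closed-interval variant is a config switch since the
  endpoint convention is genuinely ambiguous in field usage. Years past
  the end of the deposition record reuse the last recorded rate.
- **Temperature change**: difference between 5-year means (survey year
  and its four predecessors) at resurvey versus baseline. Any missing
  year in a window is an error — a silently shorter window would bias
  the change.
- **Aridity change**: same two-window difference on the annual UNEP
  aridity index AI = P/PET (higher = wetter). AI is computed per year and
  then averaged, not computed from averaged P and PET; the two orders
  differ whenever P and PET co-vary across years.

All plots in a site share the site's predictor values.

## Per-plot responses and species fates

Plot filters mirror the nested analysis designs: `richness` keeps plots
with ≥1 fixer in either survey, `pd` needs ≥2 fixers in at least one
survey (distance metrics require pairs), and `strict` needs ≥2 in both.
Genus-or-coarser identifications (e.g. `Lathyrus_sp`) are kept by default
and can be dropped with a flag; most such records are genera with no
congeneric records in the same survey, where the graft contributes nearly
the same branch length either way.

Per-species fates count, over plots, where the species was conserved
(`PC`), lost (`PL`) or gained (`PG`), giving the net change
ΔP = (PG − PL)/(PC + PG + PL) ∈ [−1, 1]. Loss and gain probabilities
default to the same occupied-plot denominator (PC + PL + PG); an
alternative conditioning on presence in the relevant survey
(PL/(PC+PL), PG/(PC+PG)) is an option, since either reading is
defensible. Plots where a species never occurred contribute nothing.

## Random-intercept mixed model

The change models are linear mixed models with a single random intercept
for study site, fitted by profiled REML. With θ = σ_site²/σ², the
marginal covariance is block-diagonal with per-site blocks I + θJ, which
invert in closed form; fixed effects are GLS at each θ and the residual
variance is profiled, so fitting is a bounded one-dimensional search over
t = θ/(1+θ) ∈ [0, 1) (Brent, absolute tolerance 1e-12 on t, with the
θ = 0 boundary checked explicitly). This makes fits deterministic and
reproducible without an external fitting library; the implementation is
validated against OLS at the boundary, ANOVA method-of-moments in
balanced designs, and statsmodels' MixedLM on general designs.

Predictors (cumulative N, ΔT, ΔAI, the baseline response, optionally
canopy-cover change) are standardized to mean 0 / SD 1, so slopes are per
SD of predictor. The baseline covariate absorbs regression to the mean.
t-tests use containment-style df = n − n_sites − (p − 1), the convention
of classical mixed-model software for between-site predictors; the exact
df rule differs across packages, so reported t and p values are
convention-dependent and a `residual` df rule is available. Collinearity
is screened with VIFs; perfectly collinear columns report `inf` with a
warning. Because PD changes are heavy-tailed, a signed cube-root response
transform (x ↦ sign(x)|x|^{1/3}, odd and monotone) is available as a
variant. Outlier screening reports |standardized residual| > 4 and
per-site leave-one-out coefficient changes but never drops data.

Guild comparisons fit per-plot guild PD on guild identity with a site
random intercept, refitting under each reference level so every pairwise
contrast (conserved−lost, conserved−gained, gained−lost) is a reported
coefficient; reparameterization invariance of the shared contrasts is a
tested identity.

## Pagel's λ

The trait (a species' loss probability, gain probability or ΔP) is
modeled as multivariate normal with covariance σ²C(λ), where C is the
Brownian matrix (C_ij = MRCA depth) and λ multiplies the off-diagonal
entries. μ and σ² are profiled analytically; λ is maximized over [0, 1]
by bounded search with both endpoints checked and boundary ties resolved
to the endpoint. Significance is an LRT against λ = 0 on χ²₁, with p = 1
by convention when the estimate is exactly at the λ = 0 boundary. On a
star tree the likelihood is flat in λ; the fit reports λ = 0 with a
degeneracy warning. Traits are used on their raw scale (probabilities are
not transformed first); with bounded traits the normality assumption is
approximate, which matches standard practice for this statistic.

## Synthetic data: what it emulates

The generator reproduces the *structure* of a continental resurvey study:

- a Yule tree rescaled to a 150 My crown, with the N-fixer trait assigned
  to ~5 whole clades totalling ~6% of a 400-species pool (nodulation is
  genus-conserved, so trait and genera are defined clade-wise);
- 53 sites × 18 plots, baselines in 1945–1985 and intervals of 44 ± 15
  years (minimum 10), matching decadal resurvey designs;
- site-level environments: an exponential deposition ramp (growth 0.055
  yr⁻¹, site-median end rate 2 g N m⁻² yr⁻¹, frozen after 2016 to
  emulate the deposition record ending before the latest resurveys) —
  chosen so the relative rate increase over a typical interval is about
  tenfold; a warming trend of 0.025 °C yr⁻¹ on an 8 °C base (relative
  increase ≈ 0.14 over an interval); stationary precipitation and PET;
- occupancy dynamics: per-species baseline occupancy with Beta
  heterogeneity (means 0.15/0.12 for fixers/non-fixers, giving ~50
  species and ~3 fixers per plot), loss by
  logit P(lost) = −0.62 + 0.05·cumN (fixers) / 0.005·cumN (non-fixers)
  + u_site with σ_site = 0.5, and background colonization at 0.035 per
  absent species (optionally aridity-linked, to probe the
  aridity-alleviates-PD-loss pattern). At typical cumulative deposition
  this yields ~70% loss of baseline fixers per plot, in the range of
  observed declines.

Presets: `null` removes both deposition effects and equalizes occupancy
(the calibration scenario for type-I error), `study` is the default
above, `strong-signal` doubles the fixer effect for demonstrations.

What the generator does **not** emulate: spatial autocorrelation within
and among sites, dispersal limitation, abundance dynamics and observer
error, per-plot survey timing within a site, or correlated environmental
drivers. Passing tests therefore show that the pipeline recovers known
effects under its own assumptions — exchangeable plots within sites,
site-level predictors, logistic occupancy loss — not that those
assumptions hold in any particular field dataset.

## Validation sizes and determinism

The test suite checks metric implementations against brute-force oracles
on 100 random trees (≤40 tips), mixed models against closed forms and
statsmodels, slope recovery at 50 sites × 20 plots over 200 replicates
(truth −0.010 on the standardized scale, site SD 0.02, residual SD 0.05),
type-I error over 400 null-pipeline replicates at 25 sites × 8 plots
(3σ binomial band around 5%), and λ recovery on 200-tip trees. These
sizes give tight Monte-Carlo error while keeping the full suite in the
low minutes; all simulations are seeded and every generator is
deterministic under a fixed seed.
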