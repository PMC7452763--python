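# Methods

## The analysis problem

Tissue samples preserved in the field (here: fish fin clips stored in DESS
— 20% DMSO, 0.25 M EDTA, saturated NaCl — or in absolute ethanol, with or
without a brief 80 °C heat treatment, at ~5 °C or ~20 °C, for 1–90 days)
degrade at rates that determine whether the extracted DNA is still usable
for long-read or long-insert sequencing. Capillary electrophoresis
quantifies this as an electropherogram: relative fluorescence (RFU) versus
fragment size (bp). Intact genomic DNA shows a high-molecular-weight
(HMW) hump above ~20 kbp; degradation moves mass into a smear around
1 kbp. `fragqc` turns a set of such traces plus a design table into (i)
per-treatment mean traces with confidence bands, (ii) AUC-based HMW
scores, (iii) a 0–10 fragmentation score per sample, and (iv) a factorial
ANOVA over the storage design.

## Cross-run harmonization (`fragqc.merge`)

Different instrument runs report slightly different size-axis point
estimates for large fragments, so traces must be harmonized before
averaging:

1. **Binning** (`bin_size`): sizes ≤ 1,000 bp unchanged; sizes in
   (1,000, 10,000] bp are **ceiled** to the next multiple of 10; sizes
   > 10,000 bp are **rounded half-up** to the nearest multiple of 100.
   The two regimes use different conventions deliberately — "round up"
   versus "round to nearest" — and both live in one function so the
   choice is isolated. The map is idempotent and monotone.
2. **Within-bin averaging**, then **clipping** of negative RFU to zero.
   Baseline-subtracted instrument output can be slightly negative;
   clipping after averaging is the default, and `clip_first` swaps the
   order since the correct order is a judgment call.
3. **Alignment**: all merged traces are placed on the union of their
   binned grids. In-range gaps are filled by linear interpolation and
   flagged; points outside a trace's observed range are left missing
   (never extrapolated).
4. **Group summaries**: per treatment group and storage time, the
   pointwise mean and a 95% band, mean ± t(0.975, n−1)·SD/√n. A Student-t
   band is the default because group sizes of 5 make the normal quantile
   indefensible; `ci_method="normal"` is available. Groups of one get a
   degenerate band.

## HMW quantification (`fragqc.hmw`)

DNA mass in a size window is proxied by the trapezoidal area under the
RFU-vs-size curve. Sizes below **250 bp** are excluded (RNA carry-over
distorts that region); the HMW window is **≥ 20 kbp** (inclusive — both
cutoffs are parameters). Window edges that fall between grid points enter
via linear interpolation of the integrand.

Per group×time: `raw_pct = 100·AUC(≥20 kbp)/AUC(≥250 bp)` and
`std_pct = 100·AUC(≥20 kbp)/max_group AUC(≥20 kbp)`. The standardization
reference is the **single global maximum** across all group×time entries
(ties broken by deterministic sort order and logged), so exactly one
entry scores 100.0. Raw % is invariant to rescaling one group's trace;
standardized % is not — the two normalizers answer different questions.
The DESS/ETOH **scale factor** per time point is
`std_pct_DESS / std_pct_ETOH`, reported at 1 decimal with full precision
retained. AUC is computed on the per-group mean trace (the alternative —
averaging per-sample AUCs — differs only through pointwise clipping and
unequal sample amplitudes).

## Fragmentation score (`fragqc.quality`)

The instrument software's Genomic Quality Number is proprietary; the
package computes a documented surrogate on the same 0–10 scale:

    gqn_surrogate = 10 · AUC(≥ threshold) / AUC(≥ 250 bp),  threshold default 10 kbp.

The threshold is user-set on real instruments and unreported in most
studies, so it is a flag (`--gqn-threshold`) and recorded in all outputs.
The score is amplitude-invariant, which makes it robust to per-sample
loading differences (and, in simulation, to per-fish amplitude effects).

## Factorial ANOVA

Fixed-effects linear model on the per-sample fragmentation score with
factors solution (2), heat (2), temperature (2) and storage time
(categorical, 5 levels) and all interactions, fit by OLS (statsmodels).
Sums of squares are **sequential (type I)** in the canonical order (main
effects, then interactions by ascending order); on a complete balanced
crossing — which the default 200-sample design is — sequential SS equal
type-II SS, and the fit asserts that equivalence instead of assuming it.
F = MS_term/MS_residual; p-values are unadjusted. A response constant to
rounding error makes every mean square 0/0; F and p are then reported
missing. Designs with empty cells reject the full-interaction model with
advice to reduce terms. The full model versus a nested reduction (e.g.,
solution only) is compared by the partial F test
F = [(SSR_r − SSR_f)/(df_r − df_f)]/MS_resid_f. Fish is deliberately not
in the model (the published analysis style uses treatment factors only);
mixed-effects modeling is out of scope.

## The synthetic generator (`fragqc.simulate`)

Each trace is a three-component log-normal mixture on the size axis —
LMW (center 150 bp, log-SD 0.35), degraded smear (1 kbp, 0.55), HMW
(40 kbp, 0.22) — scaled to a total signal mass of 2×10⁵ RFU·bp. Log-normal
humps were chosen because real smears are unimodal humps on a log-size
axis. Degradation moves mass from HMW to the degraded component
(fragmentation shortens molecules, it does not destroy them):
w_H(t) = w_H(0)·e^(−rt), with initial weights (0.2, 0.3, 0.5). The rate is
multiplicative over treatments, r = r₀ · m_sol^[ETOH] · m_temp^[room] ·
m_heat^[untreated]; defaults r₀ = 0.005/day, m_sol = 20, m_temp = 2,
m_heat = 1.5, chosen so the reference cell (DESS/cold/treated) keeps
>50% of its HMW mass at 90 days while ethanol-stored samples lose most of
theirs, and so the solution effect dominates the factorial — matching the
qualitative pattern the assay is used to detect. Per-fish amplitude is
log-normal (log-SD 0.15) and shared across a fish's samples; each
simulated run (one per time point by default, configurable) perturbs the
size axis by a multiplicative N(0, 0.005) calibration drift; detector
noise is i.i.d. Gaussian per grid point (SD 1 RFU) and can push RFU below
zero, exercising the clipping path. All randomness derives from one seed
via hashed substreams, so a (seed, config, design) triple is bit-reproducible.

Ground truth per sample records the mixture weights, the decay rate, and
the analytic HMW fraction of signal inside the analysis window
(lognormal CDFs truncated to the grid), which is exactly what the AUC
pipeline estimates.

**What the generator does not emulate:** ladder chemistry and
re-calibration, instrument optics, heteroskedastic or correlated noise,
RNA co-extraction kinetics, non-exponential decay, and fish-by-treatment
interactions. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical structure, not instrument
fidelity.

## Numerical choices and problem sizes

- Default size grid: 500 log-spaced points on [75, 60,000] bp. The
  repeated-simulation calibrations (500 null replicates, 200
  effect replicates) use a 160-point grid, which resolves all three
  components while keeping hundreds of replicates cheap.
- Trapezoid quadrature error on these grids is far below every tolerance
  asserted in the tests except pointwise identities, which use
  component-containing grids.
- AUC additivity holds to 1e-9 relative; SS decomposition to 1e-8.
- Ties in the standardization reference are broken by (group key, time)
  sort order and logged.

## Known limitations

- **Clipped-noise bias.** Clipping negative RFU to zero leaves a positive
  noise floor (mean 0.4σ per grid point) wherever true signal is ~0.
  Integrated over the wide HMW window this floors raw HMW % at roughly
  8–10% (at the default noise level) for groups whose true HMW mass has
  fully decayed, and depresses it by ~1–3 points for HMW-rich groups
  (the floor inflates the denominator there). This is a property of the
  clip-then-integrate procedure itself; interpret small raw-% differences
  near the noise floor with caution.
- The confidence bands are pointwise, not simultaneous.
- Sequential SS are only order-invariant on balanced designs; the package
  checks balance rather than silently reporting order-dependent tables.
- The fragmentation score is a surrogate: it reproduces the 0–10 scale
  and threshold semantics of instrument-software quality numbers, not any
  vendor's exact algorithm.
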