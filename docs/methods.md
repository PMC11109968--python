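# Methods

## The occupancy model

`pbmotif` models the binding of a protein to a probe as the sum of
independent Langmuir binding events at every length-*L* window of the probe.
A window starting at offset *o* has standard free energy

ΔG = ΔG₀ + Σ_p ΔΔG[p, base(o+p)]

with `ΔΔG` an *L*×4 energy matrix (columns ordered A, C, G, T) and `ΔG₀` the
unspecific binding energy, both in RT units with RT ≡ 1 (the data carry no
temperature information; only energy ratios matter for a correlation
objective). Window occupancy is `c / (c + exp(ΔG))` with protein
concentration `c`; since only `ΔG₀ − ln c` is identifiable, `c` defaults to 1
and is never fitted — the field exists so users can express literature
concentrations explicitly. Probe occupancy is the sum of window occupancies.

**Gauge.** Adding a constant to all four entries of a position while
subtracting the sum of those constants from `ΔG₀` changes no window energy.
All matrices are therefore reported in the zero-sum gauge (each position's
entries sum to zero, `normalize_matrix`), which separates specificity
(`ΔΔG`) from affinity (`ΔG₀`). The fit optimizes the matrix unconstrained and
projects the gauge on return; because the objective is gauge-invariant the
constraint never needs to bind during optimization. A corollary worth
knowing: even with `fit_dG0=False`, uniform column shifts make the effective
unspecific energy free during fitting, so the flag's practical meaning is
whether the max-occupancy penalty (below) is active.

**Double strands.** For double-stranded probes the forward and
reverse-complement windows at one offset cannot both be occupied. The default
rule sums the two occupancies and clips at 1 ("clip"); a smooth competitive
alternative `o_f + o_r − o_f·o_r` is available via `ds_rule="competitive"`.
The clip rule is the minimal reading of "at most one protein per site"; the
choice is exposed because the data rarely distinguish them.

**Overlapping sites.** Occupancies of overlapping windows are summed without
steric exclusion. This over-counts only when probes approach saturation,
which the `ΔG₀` conventions below are designed to avoid; explicit
steric-exclusion models exist but are out of scope.

## Fitting

The objective is the Pearson correlation *r* between predicted probe
occupancies and measured signals — scale- and offset-free, appropriate
because array intensities are proportional to occupancy only up to an unknown
affine map. Optimization is L-BFGS with an analytic gradient (the chain rule
through the Langmuir function and the per-window scatter of matrix entries);
tolerance 1e-6 on the objective, at most 500 iterations. Random starts draw
i.i.d. N(0, 0.5²) entries (0.5 RT is the scale of typical specificity
matrices), gauge-projected, with the starting `ΔG₀` set by calibrating the
start matrix to the configured occupancy target — a concrete replacement for
"estimate from motif length and typical energies".

With `fit_dG0=True` the objective becomes
`r − w·(max_occupancy − target)²` (default weight 10, target 1.0), which
keeps the most-occupied probe near one bound protein — used when the data
would otherwise drive the model into unphysical probe saturation. The
maximum is handled by sub-gradient at the argmax probe.

`calibrate_dG0` sets `ΔG₀` for a fixed matrix so the maximal probe occupancy
hits a target exactly (Brent root finding on a strictly decreasing function;
result within 1e-6 of target). `mae` is reported after regressing signal on
occupancy with free slope and intercept, since occupancy (proteins/probe)
and normalized scores are in different units; this makes the number
comparable with the k-mer baseline's mae.

Multi-start fitting spawns per-restart seeds from a master seed
(`numpy.random.SeedSequence`, all below 2³¹), sorts by descending training
r, and breaks ties toward lower `ΔG₀`, then lower seed, for determinism.

## The explorative workflow

Defaults follow the standard exploration recipe: 80/20 train/test split;
a balanced subset of the 4% highest- and 4% lowest-signal training probes
downsampled to at most 1000; a cross-validated motif-length scan choosing
argmax of (mean validation r)²/√L; 20 random restarts at the chosen length
compared in a 2D PCA of the gauge-projected matrices (for double-stranded
data a reverse-complement twin cluster is flagged as an internal control).
The restart motifs are then re-scored on the **full training set**, and the
best there — not on the subset — is carried into the full-train refit,
because the subset's balanced composition can mislead the ranking.

Refinement then alternates structure and refitting: flanking positions are
tried nearest-first on each side (core frozen, the new column fitted from
zeros) and kept when they raise r by ≥ 2%, with the acceptance baseline
updated as extensions are accepted — without that update, a low-quality core
lets every candidate pass and the motif balloons; borders grow by one
position per side while the terminal position's information exceeds
0.25 bit; border positions whose zeroing costs < 2% of r are pruned; each
structural change ends in a joint refit. The 2% thresholds are interpreted
as relative changes of r (Δr/|r|); an absolute interpretation is available
via `relative_changes=False`. A classification threshold of
mean + 4·sd (sample sd) of all signals is computed for diagnostic plots.

The custom-array preset (`t7_config`) differs as the small-array setting
demands: no subset (all probes used directly), 10× repeated 5-fold CV,
200 restarts, and `fit_dG0=True` with target 1.0. Signal squaring and 3′
padding with the constant-region hexamer `GTCTTG` are explicit opt-in steps
in `probeio`, not silent preprocessing — the workflow otherwise uses signals
exactly as given.

**Known limitation.** The length criterion (mean r)²/√L deliberately favours
short motifs; when a 2-mer already correlates well (common for low-
information motifs whose information concentrates on two positions) the
criterion can sit on a knife edge and select a core shorter than the true
motif, and the extension step does not always escape the resulting local
optimum. The scan table is returned precisely so users can inspect the
curve rather than trust the argmax blindly.

## Motif representation and comparison

Energies map to frequencies by Boltzmann weighting
`f ∝ exp(−β·ΔΔG)` with β = 1 in RT units (the same exponent scale as the
occupancy model; β is recorded in every report). Information content per
position is `2 + Σ f log₂ f` bits against a uniform background. The distance
between motifs is the Euclidean norm of the difference of per-base
information contributions `f·IC` — the letter heights of an information
logo — so it tracks visual logo similarity. For equal-length motifs the
distance is computed directly (a one-position shift therefore scores high,
as it should when the recovered site is genuinely displaced); for unequal
lengths `aligned_motif_distance` minimizes over zero-padded offsets and
reports the chosen offset. Logos are drawn directly with matplotlib glyph
paths; renders are deterministic for fixed input.

## The synthetic-data generator

The generator emulates a single-stranded custom-array experiment:

- **Probes**: uniform random 36-nt sequences (optionally with a constant
  central motif, mirroring arrays designed around a known site); 1000 probes
  in the scaled study, standing in for the ~3149-probe array.
- **Motifs**: random 3-nt energy matrices with total information targeted
  uniformly in 1–5 bits. Frequency rows are symmetric-Dirichlet draws whose
  concentration is tuned by bisection (re-using one set of uniforms through
  the Gamma quantile function, so information varies monotonically with
  concentration) to within 0.1 bit of target, capped at 200 iterations;
  energies are −log f, gauge-projected, with frequencies floored at 1e-12.
- **Signals**: exact model occupancies with `ΔG₀` calibrated so the
  most-occupied probe carries 1.2 proteins (no unphysical oversaturation);
  Gaussian noise with sd k·0.05 at multipliers k = 0/1/2/4, clipped at zero.
  The 0.05 base sd on the 0–1 score scale is the package's declared stand-in
  for replicate-derived variability — `estimate_noise_sd` (pooled per-probe
  replicate sd) is what one would run on real replicate tables. The noise
  distribution and the zero-clipping are explicit modelling choices;
  alternatives (renormalization, heteroscedastic noise) are not modelled.
- **Recovery**: per motif and noise level, 10 random-restart fits; the
  best-r fit is scored by r against the (noised) signals and by information
  distance to the truth.

What passing these simulations does *not* show: real arrays have
probe-composition biases, positional signal bias, spatial artifacts, and
scanner saturation, none of which are generated here; recovery rates on
synthetic data are an upper bound on real-data performance.

## Numerical choices

- Window energies are capped at 700 RT before exponentiation (occupancy
  underflows smoothly to zero beyond that).
- Degenerate inputs fail loudly: constant signals or constant occupancies
  raise a dedicated error rather than returning r = 0.
- PCA of identical restart matrices returns all-zero coordinates without
  calling the decomposition (zero-variance guard).
- The k-mer baseline selects its LASSO penalty by 5-fold CV over a log grid
  (1e-6…1) unless given; after truncation to the top-n weights the model is
  refit on the surviving features (non-negative least squares when the
  non-negativity option is on).
- All randomness flows from explicit seeds through `SeedSequence` spawning;
  every derived seed is reduced below 2³¹.

## Problem sizes

The bundled validation study runs 20 motifs × 4 noise levels × 10 restarts
on 1000 probes (the package's chosen benchmark size, ~2 minutes on one CPU);
the same machinery scales to the 100-motif study and to full arrays by
changing `SimulationSpec` fields. The benchmark script
(`scripts/acceptance.py`) uses the noiseless arm of the same protocol.
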