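# Methods

## Release model and its assumptions

The forward model is the plane-sheet solution of Fick's second law for a
film of thickness $d_P$ (cm) with uniform initial loading, a perfect-sink
solvent on one face and an impermeable backing on the other (one-way
release):

$$f(\tau) = 1-\sum_{n\ge 0}\frac{8}{(2n+1)^2\pi^2}
  e^{-(2n+1)^2\pi^2\tau/4},\qquad \tau = \frac{D\,t}{d_P^2}.$$

The $4d_P^2$ denominator encodes the one-exposed-face geometry: the full
thickness plays the role of the half-thickness of a doubly exposed sheet.
Assumptions inherited by everything downstream: constant $D$ (no
concentration dependence), fixed geometry during release (swelling is
measured separately, not coupled), and instantaneous surface equilibrium.
Anomalous-transport models (Korsmeyer–Peppas, Weibull) are deliberately out
of scope.

### Series evaluation

Terms decay like $e^{-n^2}$, so truncation is adaptive: summation stops
when the next term's magnitude falls below `term_tol` (default $10^{-14}$),
which needs $\lceil\frac12\sqrt{4\ln(8/(\pi^2\,\mathrm{tol}))/(\pi^2\tau)}\rceil$
terms — about 36 at $\tau=0.01$, about 1800 at $\tau=10^{-6}$ — capped at
$10^6$ with an explicit convergence error. Below $\tau=10^{-6}$ the
complementary short-time representation $f\approx(2/\sqrt\pi)\sqrt\tau$ is
used; at the crossover the two forms agree beyond double precision (the
neglected image terms are $O(e^{-1/\tau})$). Results are clamped to
$[0,1]$; $f(0)=0$ exactly. The dimensionless half-release time is
$\tau_{1/2}\approx 0.19676$; `time_to_fraction` inverts $f$ by Brent
bracketing on $\tau$.

Note the equilibrium tail: $1-f(\tau)\approx\frac{8}{\pi^2}e^{-\pi^2\tau/4}$
is $1.6\times10^{-11}$ at $\tau=10$ and drops below $10^{-12}$ only past
$\tau\approx 11.3$ — relevant when asserting "fully released" numerically.

## Estimating D

`fit_D` minimises $\mathrm{RMSE}(f_\mathrm{obs}, f_\mathrm{model})$ over
$\log_{10} D$, default bounds $[-14,-4]$ (cm²/s decades). Measured film
coefficients span four orders of magnitude, so the log scale keeps the
problem well conditioned. The minimiser is a 60-node coarse grid followed
by bounded Brent refinement between the bracketing nodes — deterministic,
and grid-first protects against the objective's flat plateaus far from the
basin. Convergence failures are flagged on the result, never silent.
Unweighted residuals match the plain-RMSE reporting convention for such
fits; weighted variants were deliberately deferred.

Normalisation: curves built from raw amounts divide by the equilibrium
amount $M_\infty$, by default the mean of the final three samples provided
their relative spread is < 2% (a warning otherwise). Alternatively
`m_inf_mode="co-estimate"` profiles a free multiplicative scale on the
fractions, which has a closed-form optimum at each $D$, so co-estimation
costs nothing extra. Points at $t=0$ are retained (the model passes through
zero exactly); duplicate times are averaged on input.

Uncertainty is by residual-resampling bootstrap (percentile 2.5/97.5,
$B\ge100$, seed mandatory). Refits search ±1.5 decades around the point
estimate (clipped to the user bounds): residual noise of the magnitude seen
here moves $\hat D$ far less than a decade, and the narrower window keeps
$B=500$ refits under a second. Measured behaviour (in the test suite): with
σ = 0.03 noise on 20-point schedules, nominal-95% intervals cover the truth
in ≥ 90 of 100 replicates, and the median absolute relative error of
$\hat D$ is ~2.5%.

## Layered decomposition

Series resistance $d/D=\sum_i d_i/D_i$; for two layers the ratio form
$D_1/D_2=(D_1/D-d_1/d)/(1-d_1/d)$ requires $D_1/D>d_1/d$, violated inputs
raise a degenerate-geometry error naming the inequality. $D_2$ is derived
from that ratio (not from the resistance subtraction independently) so the
stored ratio and $D_1/D_2$ agree to the last bit. The thickness share
$d_1/d$ is an input measured from cross-section micrographs; no image
analysis is attempted.

Two numerical facts worth knowing:

- `effective_D` clamps its final rounding into $[\min_i D_i,\max_i D_i]$ so
  the harmonic-mean bound holds exactly in floating point.
- Recovering the slow-resistance layer is ill-conditioned when its
  resistance share is tiny: a 1-ulp perturbation of $D$ is amplified by the
  layer-resistance contrast (at contrast $10^4$, ~$10^{-12}$ relative error
  is intrinsic to float64). The well-conditioned invariant — composing the
  decomposition returns $D$ — holds to $10^{-12}$ regardless.

For the published two-layer films, only film G's printed ratio (13.13) is
exactly reproducible from its printed inputs. Films GA and GC print 13.47
and 13.27, but recomputing from the two-digit $d_1/d$ values (0.73, 0.74)
gives 13.65 and 13.50; both printed values are consistent with unrounded
thickness shares near 0.726 and 0.735. The package reproduces G and
documents this rounding sensitivity rather than forcing GA/GC.

## Random-walk check

`simulate_walk` draws step directions as normalised 3-D Gaussians (uniform
on the sphere — the hop picture of diffusion in a polymer specifies no
lattice, and the isotropic continuum walk has the closed-form moment
$\mathbb E[\mathrm{MSD}(n)] = n\ell^2$). MSD is displacement from the
origin, matching the Einstein definition, not a time-averaged lag MSD.
`estimate_D_from_msd` fits a through-origin slope and divides by six;
per-walker MSD variance is $\le\frac23 n^2\ell^4$, so the estimate's
standard error shrinks as $1/\sqrt N$ (at $N=10^4$, $T=10^3$ the recovery
of $\ell^2/6\,dt$ is within 2%). The two-timescale residence/hop picture is
represented only through $dt$ = mean time per displacement; explicit
waiting-time distributions are out of scope, and the default step
parameters are illustrative, not molecular values.

## Swelling

$s=(m_t-m_0)/m_0$, negative under net mass loss (observed down to about
−0.06 for alginate films in near-anhydrous ethanol), bounded below by −1.
Equilibrium detection is a package decision (the source experiments assert
equilibrium without a rule): the first three-point window whose consecutive
relative changes are both < `rel_tol` (default 2%), reporting $s$ at the
window's end. The rule presumes sampling intervals comparable to the uptake
timescale, as in sparse gravimetric schedules; oversampling a slow
transient (interval ≪ uptake time constant) can trigger the window before
the plateau. If no window qualifies the final $s$ is returned flagged
`equilibrated=False`.

## Synthetic data: what it emulates and what it does not

Generated release curves are model fractions at a sampling schedule plus
i.i.d. Gaussian noise clipped to $[0,1]$. Defaults, fixed once:

- **σ = 0.03** on the fraction scale — the magnitude of the published
  goodness-of-fit RMSEs (0.019–0.10) for these films. A heteroscedastic
  option σ ∝ √(f(1−f)) exists but is not the default.
- **Schedule**: 20 log-spaced times spanning $\tau\in[0.01,2]$ for the
  scenario's $(D,d_P)$ — covers the informative rise of the sigmoid; the
  real sampling schedule was not published, so this is a package choice.
- **Solvent series**: $\log_{10}D$ interpolated linearly in the water
  fraction $w$ between anchors at $w=0$ and $w=1$ (printed coefficients
  change by orders of magnitude across solvents), with the monotone
  direction enforced against the declared profile: decreasing for
  plasticiser-rich films whose $D$ collapses as water blocks the migrant,
  increasing for tightly crosslinked films that water swells open.

Every artifact carries its generating parameters, schedules that never
enter the informative band 0.05 < f < 0.95 warn about weak
identifiability, and clipping beyond 1% of points is logged.

What passing tests on these data do **not** show: robustness to
heteroscedastic or autocorrelated measurement error, to $M_\infty$ drift
(evaporation), to non-Fickian transport, or to the real (unknown) sampling
schedule. The synthetic loop validates the estimators under the model's own
assumptions, no more.

## Statistics

One-way ANOVA (scipy `f_oneway`) with an explicit degenerate-data error
when every observation is identical. Pairwise comparison is Tukey HSD on
the studentized range (scipy `tukey_hsd`, Tukey–Kramer for unequal group
sizes — replicate counts in the source tables are unstated). The compact
letter display uses insert-and-absorb: start with one column holding all
groups; for each significant pair, duplicate every column containing both
and delete one member from each copy; absorb subset columns. By
construction two groups share a letter iff their comparison is
non-significant. Letters are ordered by the largest group mean contained in
each column. Null calibration (1000 seeded simulations, 4 groups × 5): the
type-I rate at α = 0.05 lands at 0.063, inside [0.03, 0.07]. The source
tables' exact letters are not reproducible — their replicate-level data
were never published.

## Units, I/O and determinism

Internal units are cm, s, cm²/s throughout; thickness enters and prints in
mm (the tabulation convention) and is converted once at the boundary.
Delimited release/mass files are comma- or tab-separated with a header
(`time_s` + `fraction` | `amount` | `mass_g`), decimal point only;
fractions within 0.05 outside $[0,1]$ are clipped with a logged warning
naming the rows, farther outside is a parse error. Results tables are CSV
plus a JSON sidecar with full-precision values, the seed, a config hash and
the package version; identical config + seed yields byte-identical output.
Every stochastic routine takes an explicit seed and refuses to run without
one.

## Problem sizes in the shipped checks

The packaged verification uses: 200-point $\tau$ grids against a
$10^5$-term brute-force series sum ($<10^{-10}$ agreement), $10^3$ random
two-layer systems, a $10^4$-walker × $10^3$-step ensemble for the Einstein
check, 200 noisy-fit replicates across the 12-film reference grid, 100
bootstrap-coverage replicates at $B=500$, and 1000 ANOVA null simulations —
sizes chosen so the full loop stays comfortably interactive on one core
(~2 minutes) while keeping Monte-Carlo error well below the asserted
margins.

## Known limitations

- Constant-$D$ Fickian transport only; no swelling-coupled moving
  boundary, no partition-coefficient modelling at interfaces.
- $d_1/d$ must be supplied; no micrograph segmentation.
- The equilibrium-swelling rule is sampling-rate dependent (above).
- Bootstrap intervals are percentile-type and mildly undercover at small
  $n$; they quantify noise, not model misspecification.
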