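# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Units

Electrophysiology uses a self-consistent small-signal system: mV, MΩ, pF,
nA, ms. Then mV/MΩ = nA, MΩ·pF = µs, and admittances come out in µS =
nA/mV. Charge is in fC (pF·mV). Displacements are nm; stiffness units are
opaque and carried from the fiber calibration constant k_f. All exported
files carry unit suffixes in their column names.

## Synthetic expression studies

Replicate RNA-seq counts are generated as a gamma–Poisson (negative
binomial) mixture: gene g has a lognormal baseline expression level
(ln-RPKM ~ Normal(1.5, 2.5), so the median is ≈ 4.5 RPKM and a left tail
falls below the 0.1-RPKM background cutoff, as in real libraries), a gene
length uniform on 500–4000 bp, and expected counts
µ = RPKM·length·library/10⁹ with library size 2·10⁷ reads. Counts are
Poisson(Gamma(1/φ, µφ)) with dispersion φ = 0.05 by default — a typical
between-replicate value for inbred animals; RPKM is then recomputed from
the drawn counts, so the normalization path is exercised end to end.

Aged-group effects are planted multiplicatively: exactly
round(frac_up·n_genes) genes get +effect_log₂FC (default +2, i.e. 4-fold)
and round(frac_down·n_genes) get −effect_log₂FC, drawn independently per
cell type unless an explicit planted set is given. Defaults frac_up = 0.10,
frac_down = 0.20 reproduce the qualitative excess of downregulated genes in
aged hair cells. Truth labels are attached to the study object and written
as a sidecar JSON.

Each generator owns a single `numpy.random.Generator` seeded explicitly;
equal seeds give byte-identical outputs and there is no global RNG state.

What the generator does **not** emulate: per-gene dispersion trends,
library-size variation between samples, batch effects, correlated gene
modules, and effect-size distributions (all planted effects share one
magnitude). Tests passing on these data show the estimators are correct
under the stated model, not that the model captures every property of real
libraries.

## Expression filtering and differential expression

- Background cutoff: a gene is expressed in a (cell type, age) group when
  the **mean** replicate RPKM is **strictly** greater than 0.1. Strictness
  at the boundary is a convention (the cutoff itself is background);
  both the cutoff and an any-replicate mode are configurable.
- The per-gene test is a one-way fixed-effects ANOVA on log₂(RPKM + c),
  pseudocount c = 0.01 — small against expressed levels but regularizing
  zeros. For two groups the F statistic equals t² of the pooled-variance
  t-test and the p-values coincide, which the tests verify as an algebraic
  identity. Degenerate rows (zero within-group variance) give p = 1 for
  equal means and p = 0 otherwise rather than crashing.
- The Benjamini–Hochberg family is exactly the set of genes expressed in at
  least one age for that cell type; FDR values are NaN outside it.
- Classification is inclusive at both thresholds (|log₂FC| ≥ 1,
  FDR ≤ 0.10) with the sign convention log₂FC = aged/young, so
  downregulation with age is negative.
- BH and Holm–Šidák adjustments are delegated to
  `statsmodels.stats.multitest.multipletests`; worked examples and a
  brute-force step-down oracle pin the expected outputs in the tests.

## Gene-set operations

"Top" rankings are not uniquely defined by the headline counts they
summarize, so the package picks explicit conventions and exposes them:
common lists between two cell types rank by the *smaller* |log₂FC| of the
pair (a gene is only as interesting as its weaker change), single-table
lists by |log₂FC|, ties broken lexicographically on the gene symbol.
Over-representation uses the upper-tail hypergeometric probability
P(X ≥ overlap) with BH correction across categories; gene identity is by
case-sensitive symbol with no alias resolution. The bundled annotation
table (`data/demo_annotations.tsv`) is a small demonstration fixture, not a
curated resource.

## Voltage-clamp simulation

The patch circuit is a series resistance Rs into a membrane with resistance
Rm and voltage-dependent capacitance

  C(V) = C_lin + (Q_max/α)·eˣ/(1+eˣ)²,  x = (V − V_pk)/α,

integrated as C(V_m)·dV_m/dt = (V_c − V_m)/Rs − V_m/Rm with fixed-step
classical Runge–Kutta at the 50 kHz sample rate (ω·dt ≈ 0.1 at f₂, so the
integrator error is far below the estimator tolerances; validated against
the closed-form admittance of the linear circuit to < 0.05%). The recorded
current is I = (V_c − V_m)/Rs, or the total membrane current when Rs = 0
(the membrane then follows the command exactly). Gaussian current noise of
configurable RMS is added at the samples.

Protocol: sines of 10 mV peak at nominal 390.6 and 781.2 Hz on DC levels
−140…+60 mV in 10 mV steps. Each analysis window spans 10 f₁ cycles; the
stimulus frequencies are snapped to the integer-cycle DFT grid of that
window (390.625/781.25 Hz at 50 kHz), so Fourier coefficients are exactly
leakage-free. Each DC level starts from its DC steady state and includes a
2-cycle settle window, excluded from analysis, so the RC step transient
(τ ≈ Rs·C ≈ 70 µs) cannot bias the admittances.

## Capacitance estimation and Boltzmann fitting

Per segment, Y(f) = I(f)/V(f) from the DFT coefficients at f₁ and f₂ of
the detrended command and current. Writing Z = 1/Y, the membrane branch
satisfies G(f) = 1/(Z(f) − Rs) = 1/Rm + jωCm, so Re G is frequency
independent: Rs is found by bracketed root finding on
Re G(f₁) − Re G(f₂) over [0, min Re Z), and Rm, Cm follow in closed form.
The residual reported is the worst relative deviation of the refitted model
admittance; pairs with residual above 5% raise a model-mismatch error (per
segment this flags, rather than aborts, the series). The reported membrane
potential is first-order corrected for the DC drop across Rs
(v = dc − I_dc·R̂s); the sinusoidal excursion is *not* phase-corrected —
a documented limitation of the point-level view.

Two estimators fit the Boltzmann:

1. **Point-level fit** (`fit_boltzmann`): nonlinear least squares of Cm(v)
   with multi-start initialization (α₀ ∈ {20, 33, 50} mV, C_lin₀ = min Cm,
   V_pk₀ = argmax Cm, Q_max₀ = 4α₀·(max−min)) and bounds Q_max ≥ 0, α > 0,
   C_lin > 0. Because the measured Cm is a cycle average of C(V) over the
   ±10 mV two-sine excursion, the apparent bell is slightly widened
   (≈ +1% on α at α = 33 mV); when points carry their membrane-level
   excursion amplitudes the model is averaged over the same excursion,
   removing most of that bias. A fit whose V_pk falls outside the measured
   span is flagged unbracketed with a warning.
2. **Full-waveform fit** (`fit_nlc_recording`), the pipeline default: with
   f₂ = 2f₁, the quadratic term of the nonlinear charge mixes the two
   stimulus bins (f₁+f₁→f₂, f₂−f₁→f₁), which biases the per-segment RC
   solve wherever dC/dV is large — an irreducible property of this
   protocol at finite amplitude. The full-waveform estimator therefore fits
   all six parameters (Q_max, α, V_pk, C_lin, Rs, Rm) directly to the
   measured admittance pairs through a forward model of the measurement
   chain: the periodic steady state of the clamp ODE at each DC level is
   computed by spectral collocation on one f₁ cycle with Newton iteration,
   and model admittances are read off exactly as the analysis reads the
   data. This recovers all parameters to ≈ 10⁻⁵ relative on noise-free
   recordings and ≈ 0.2% (median Q_max) at 5 pA RMS noise, and yields Rs
   and Rm estimates as a by-product.

Model identities used as oracles: peak height C(V_pk) − C_lin =
Q_max/(4α); symmetry about V_pk; ∫(C(v) − C_lin)dv = Q_max; charge density
Q_max/C_lin invariant under joint rescaling. The slope factor is
parameterized in mV (α = kT/ze); charge density is fC/pF.

## Axial stiffness

The series-spring relation k_c = k_f(L_f − L_c)/L_c is inverted by the
generator (L_c = k_f·L_f/(k_f + k_c)) and applied by the analysis.
Amplitudes are estimated as 2|DFT coefficient|/N at the drive frequency on
the detrended trace — this rejects DC offsets and broadband noise, and is
exact when the window holds an integer number of drive cycles (the
generator snaps the drive frequency to guarantee this). L_c = 0 is a
division error (an infinitely stiff cell); L_f < L_c is non-physical for a
passive load and is reported as negative stiffness with a flag rather than
silently clipped. Note the stiffness unit printed in this field's reports
is sometimes given as nN/m although typical OHC values in the literature
are mN/m-scale; the package treats stiffness units as opaque and consistent
with k_f rather than correcting them.

## Cytology

Survival percentages are 100·aged/baseline per (location, cell type) with
exact location matching (no interpolation along the cochlea); a zero
baseline count yields a missing value, an unmatched location an error.
Group comparison defaults to the classical pooled-variance Student t-test
(Welch behind a flag). The multiple-comparison correction is step-down
Holm–Šidák: sort ascending, adj₍k₎ = max_{j≤k} 1 − (1 − p₍j₎)^(m−j+1),
clipped to 1. A full two-way ANOVA is deliberately omitted: the reported
quantities are the pairwise comparisons after correction. Fluorescence fold
changes compare the per-cell mean integrated density (gray value × area)
of the aged group to baseline, per target.

## Pipeline and reproducibility

A single validated config (unknown keys rejected at every level) drives the
stages in dependency order (expression → DEG → gene sets; NLC, stiffness
and cytology independently). Per-stage seeds are derived from the run seed
by fixed small offsets. The JSON report contains no timestamps, so a given
config + seed reproduces byte-identical reports; the config hash is the
SHA-256 of the canonical JSON form of all semantic fields. A failed stage
is recorded as failed and independent stages still run; exit codes are 0
(success), 1 (validation), 2 (stage failure).

Default problem sizes (2000 genes × 3 replicates; 21 DC levels × 12 f₁
cycles at 50 kHz; 20 fiber cycles at 10 kHz; 6 cochleogram locations;
30 cells per fluorescence group) keep a full run around a second while
leaving all estimators comfortably inside their target tolerances.

## Known limitations

- The DEG test is a per-gene ANOVA on log-transformed RPKM, not a count
  GLM or moderated-variance model; at n = 3 replicates its power profile
  differs from empirical-Bayes pipelines.
- The NLC model is the two-state Boltzmann only; tension-dependent or
  higher-order prestin models are out of scope.
- Series-resistance correction of the reported potential is DC-only.
- The cochleogram and fluorescence generators draw independent cells and
  locations; spatial correlation along the cochlea is not modelled.
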