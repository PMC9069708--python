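# cochlear-aging

A quantitative pipeline for studies of biological aging in cochlear hair
cells. Age-related hearing loss is driven largely by degeneration of the
inner hair cells (IHCs, the sensory receptors) and outer hair cells (OHCs,
the cochlear amplifiers); characterizing it combines cell-type-resolved
transcriptomics with single-cell biophysics and cytology. This package
implements the full analysis chain as tested, reusable code, and ships
synthetic-data generators with known ground truth so every stage can be
validated end to end without any external data.

## What it computes

**Transcriptomics.** Expression tables (genes × replicate samples) are
normalized as RPKM = reads · 10⁹ / (gene length in bp · library size). A
gene is *expressed* in a (cell type, age) group when its mean replicate RPKM
exceeds a background cutoff (default 0.1 RPKM). A gene is *differentially
expressed* between ages when it is expressed in at least one age and

  |log₂FC| ≥ 1  and  FDR ≤ 0.10,

with log₂FC = log₂((aged + c)/(young + c)) for pseudocount c, the per-gene
p-value from a one-way ANOVA on log₂(RPKM + c) (for two groups, F = t² of
the pooled-variance t-test), and Benjamini–Hochberg adjustment over the
tested genes. Downstream set logic builds ranked top-N lists of genes
changed in both hair-cell types or exclusively in one, concordance with a
reference cell type (stria vascularis), and hypergeometric
over-representation of functional categories.

**Nonlinear capacitance (NLC).** OHC electromotility has an electrical
signature: a bell-shaped, voltage-dependent membrane capacitance from
prestin charge movement. A two-sine command (10 mV peaks at f₁ = 390.6 Hz
and f₂ = 2f₁) rides on a series of DC levels; the complex admittance at
both frequencies over-determines the recording circuit (series resistance
Rs, membrane resistance Rm, membrane capacitance Cm), which is solved per
DC level. Cm(V) is then fitted with the two-state Boltzmann derivative

  Cm(V) = C_lin + (Q_max/α) · eˣ/(1+eˣ)²,  x = (V − V_pkcm)/α,

giving the maximum nonlinear charge Q_max (fC), slope factor α (mV),
voltage at peak capacitance V_pkcm (mV), linear capacitance C_lin (pF), and
charge density Q_max/C_lin (fC/pF). The pipeline estimator additionally
refines all parameters against the raw admittances through a periodic
steady-state model of the clamp circuit, which removes the harmonic-mixing
bias inherent to the f₂ = 2f₁ protocol.

**Mechanics.** OHC axial stiffness from calibrated-fiber loading:
k_c = k_f (L_f − L_c)/L_c, with free and loaded fiber amplitudes L_f, L_c
read off the Fourier coefficient at the drive frequency.

**Cytology.** Cochleogram survival percentages versus the young baseline at
matched cochlear locations; group statistics (pooled-variance Student
t-tests, step-down Holm–Šidák correction); fluorescence fold changes of
integrated density (mean gray value × area).

## Worked example

Simulate a voltage-clamp recording of an OHC with known NLC (Q_max = 800 fC,
α = 33 mV, V_pkcm = −70 mV, C_lin = 7 pF; Rs = 10 MΩ, Rm = 500 MΩ) under
the two-sine protocol with 5 pA RMS current noise, then estimate everything
back:

```python
from cochlear_aging import (
    BoltzmannParams, CircuitParams, TwoSineProtocol,
    gen_voltage_clamp_recording,
)
from cochlear_aging.nlc import fit_nlc_recording

rec = gen_voltage_clamp_recording(
    CircuitParams(rs=10, rm=500, clin=7),
    BoltzmannParams(qmax=800, alpha=33, vpk=-70),
    TwoSineProtocol(), noise_rms_pA=5.0, seed=42,
)
fit = fit_nlc_recording(rec)
print(f"Qmax   = {fit.qmax:7.1f} fC")
print(f"alpha  = {fit.alpha:7.2f} mV")
print(f"Vpkcm  = {fit.vpk:7.2f} mV")
print(f"Clin   = {fit.clin:7.3f} pF")
print(f"charge density = {fit.charge_density:6.2f} fC/pF")
```

prints

```
Qmax   =   801.1 fC
alpha  =   33.03 mV
Vpkcm  =  -69.98 mV
Clin   =   6.996 pF
charge density = 114.51 fC/pF
```

i.e. all four Boltzmann parameters are recovered to a fraction of a percent
at realistic noise; the charge density (prestin density proxy) follows as
Q_max/C_lin.

The whole pipeline runs from one config:

```sh
cochlear-aging run --config src/cochlear_aging/data/demo_config.yaml \
    --seed 1 --outdir out/
```

which writes per-stage artifacts (count/RPKM TSVs, DEG tables, ranked gene
lists, Cm–V points, survival and fold-change tables) plus a machine-readable
`report.json` with expressed-gene counts, DEG triples (n_deg = n_up +
n_down), planted-truth recovery rates, fitted NLC parameters, stiffness, and
survival summaries. Identical config + seed gives byte-identical reports.

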