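# Methods

This note documents the models, numerical choices and defaults behind
`peatdom`, and what the synthetic-data tests do and do not demonstrate about
real measurements.

## Mass arithmetic

All masses are monoisotopic sums over a pinned constants table (C 12.000000,
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117, P 30.97376200 Da);
ions are singly charged and the electron mass is folded into the proton
constant (1.00727646 Da), an approximation below 1e-6 Da. The decarboxylation
reference mass computed from this table is CO2 = 43.98983 Da (5 d.p.).

## Formula assignment

Assignment follows the compound-identification-algorithm pattern for natural
organic matter: neutralize (±proton), enumerate every CHNOSP composition
whose exact mass lies within the tolerance, screen, select.

*Enumeration.* The search grid spans the configured element limits (defaults
C ≤ 60, H ≤ 120, N ≤ 3, O ≤ 30, S ≤ 2, P ≤ 2; neutral mass 100–1000 Da —
high-resolution DOM analysis is unreliable below ~100 Da). Hydrogen is solved
per query rather than enumerated: adjacent H counts differ by 1.008 Da, far
beyond any ppm tolerance below 1000 Da, so this is exactly equivalent to the
full brute force (asserted against an independent grid search in the tests).

*Screening.* Candidates must satisfy 0.3 ≤ H/C ≤ 2.25 and O/C ≤ 1.2, the
SENIOR/nitrogen-rule parity (2C + N + P + 2 − H even and ≥ 0, i.e. integer
non-negative DBE), and three DOM plausibility rules, each configurable:
DBE − O ≤ 10 (drops oxygen-free polycyclic compositions that arise only as
isobaric artifacts), phosphorus only as phosphate esters (O ≥ 4P), and no
S–P co-occurrence (organosulfur phosphates are essentially absent in natural
DOM).

*Selection.* Among surviving candidates the score
`|Δm| + 0.21 mDa·(N+S) + 0.15 mDa·P` is minimized; exact ties break on fewest
heteroatoms, then element counts. The handicap expresses the prior that
heteroatom-rich compositions are rarer in DOM, so they must fit the mass
decisively better to win. The weights are calibrated against the isobaric
fine structure of the default search space: the closest doublets exchanging
heteroatoms sit at 0.651 mDa (±2N+S for 8C−4H−2O), 0.513 mDa (±2N for
13C−8H−11O), 0.380 mDa (N2P↔CHOS family) and 0.133 mDa (S↔P exchange), and
each handicap combination is kept strictly below the corresponding spacing.
Consequently an *exact* mass match is never displaced — noise-free
assignment recovers the generating formula with certainty — while with mass
noise the simpler composition correctly wins the ambiguous middle ground.

*Accuracy envelope.* With 0.5 ppm (1σ) Gaussian mass error and a 4σ matching
tolerance, recovery on 500-compound synthetic libraries averages ≈ 99%. The
residual ~1% sits on the sub-mDa doublets above: at 400–700 Da a 0.4–0.65 mDa
spacing corresponds to 0.6–1.6 ppm, within reach of 2–3σ mass errors, and no
mass-only selector can resolve those cases reliably. Real instruments break
the tie with isotopic fine structure or sub-0.3 ppm internal recalibration;
both are out of scope here (no 13C filtering, no recalibration), so the
matching tolerance should always be set to ≥ 3–4× the expected mass error
and borderline assignments treated as provisional.

## DOM indices

NOSC, DBE and the aromaticity index are pure element-count arithmetic (see
README for the formulas); AI uses the original Koch–Dittmar form by default
with the carboxyl-corrected AImod behind a flag, since which variant a given
study means by "aromaticity index" is often unstated. Van Krevelen classes
use rectangular H/C–O/C boxes with half-open (lo, hi] intervals so boundary
compositions land deterministically in the lower-O/C class; the box borders
follow common DOM-literature conventions and are passed in as data, not
hard-coded chemistry. Per-sample summaries are unweighted means over assigned
formulas: FTICR-MS identifies compounds but does not quantify them, so
intensity weighting would suggest precision the data lack.

## Transformation counting

Within a sample, every unordered compound pair contributes one |Δm|; a pair
increments every moiety whose reference mass lies within the absolute
tolerance (default 1 mDa — ppm would be ill-conditioned for light moieties
such as H2 at 2.016 Da). Pairs are unordered and gain/loss direction is not
inferred; a compound may participate in many pairs, so totals can exceed the
compound count. The packaged starter database holds ~40 literature-standard
moieties (decarboxylation, (de)hydration, hydrogenation, oxygenation,
methylation, amino-acid and sugar condensations, S/P groups, and composites
like methanol−H2O); study-specific databases load from `name,formula,
exact_mass` CSV with formula/mass consistency enforced at 1e-5 Da.

## Optics

Spectral slopes are estimated by least squares on ln a(λ) over 275–295 and
350–400 nm and negated; regression is the robust reading of a "first
derivative of the log spectrum" (a finite-difference mode exists for
comparison, and the two agree exactly on clean exponentials). SUVA254 uses
decadic absorption coefficients (a = A/l). EEM processing excises the two
Rayleigh orders (±14 nm) and the water-Raman band (3400–3600 cm⁻¹ shift,
±16 nm pad) with linear interpolation along emission; these widths remove
ridge energy to < 1% while perturbing Coble-window fluorophores by < 0.1% in
the synthetic recovery tests. Raman normalization divides by the blank's
Raman peak area (ex 350 nm, em 371–428 nm), cancelling instrument gain; QSE
conversion is a linear calibration. Coble windows (A: ex 250–260/em 380–460,
B: 270–280/300–320, T: 270–280/330–350, M: 290–310/370–410, C: 320–360/
420–460 nm) are configuration data — source conventions vary — and areas are
2-D trapezoids. Inner-filter correction is not applied; the workflow assumes
samples diluted to low absorbance, with a dilution-factor field honored in
metadata.

## FTIR

Each band (1030, 1510, 1630, 1720 cm⁻¹ at ±40 cm⁻¹; 2850, 2920 cm⁻¹ at
±25 cm⁻¹ to avoid mutual overlap) is corrected by the straight line joining
local absorbance minima found within ±15 cm⁻¹ of the window ends, negative
residuals clipped, and the trapezoidal band area divided by the whole
spectrum's end-to-end baseline-corrected area. Fractions are therefore
scale-invariant and bounded by [0, 1]. ATR and instrument-level corrections
are assumed applied upstream.

## Gas dynamics

Headspace ppm converts to µmol via n = ppm·P·V/(R·T) with
R = 0.0820574 L·atm·mol⁻¹·K⁻¹; the default vial is 125 mL with 40 g peat +
40 mL water (0.085 L headspace) at 18 °C, overridable per sample. Production
rates are OLS slopes of cumulative amount vs day (≥ 3 points required), in
µmol per gram dry weight by default with a per-vial mode, since reporting
conventions differ. CO2:CH4 ratios are averaged over the day windows 0–5,
20–30, 45–55, 70–80, 90–100 in cumulative-amount form by default, with an
incremental-production mode, as both readings are common. αC thresholds
(acetoclastic < 1.055, hydrogenotrophic > 1.065, mixed between, closed
interval) follow the conventional interpretation and are configuration;
α < 1 is flagged but classified. Dissolved-phase partitioning (Henry's law,
carbonate speciation) is not modeled — accounting is headspace-only — and
group comparisons (Welch t, one-way ANOVA) are reported per window without
multiplicity correction by default.

## Synthetic data generator

The generator emulates the seven input streams with invertible models:

- *Compound libraries.* Per-compound O/C and H/C are drawn around habitat
  targets (σ 0.08 and 0.12) and recentred so the drawn means equal the
  targets; carbon is uniform on 8–30, nitrogen 0–2 with lability-scaled
  probability, S (5%) and P (3%) mutually exclusive single atoms, hydrogen
  rounded to the DBE-parity lattice. Every formula passes the default
  screening rules, so assignment round trips are exact by construction.
  The three habitat presets (palsa/bog/fen with rising H/C, lability and
  library size) are illustrative contrasts, not field claims.
- *Peak lists.* One peak per formula with Gaussian ppm error and log-normal
  intensity; noise peaks are uniform on 100–1000 Da outside a 3σ exclusion
  zone around every true mass, so false-positive counts are well-defined.
- *Gas series.* Amounts are rate·t plus Gaussian noise truncated at zero
  (negligible bias away from t = 0 at the default noise), converted to ppm
  through the vial model; δ13CH4 is constant and δ13CO2 is constructed so αC
  holds exactly at every time point.
- *UV-Vis.* A single exponential a0·e^(−S(λ−240)), making the slope ratio
  exactly 1 — deviations isolate estimator error.
- *EEMs.* Sums of 2-D Gaussians (σ_ex 8 nm, σ_em 18 nm) at canonical Coble
  coordinates plus Rayleigh/Raman ridges; the blank carries ridges only.
  Closed-form Gaussian window masses provide the analytic oracle.
- *FTIR.* Gaussian bands (σ 12 cm⁻¹) with area equal to the weight, on a
  polynomial baseline.

What passing these tests shows — and does not. The recovery chain verifies
the estimators are unbiased and correctly implemented under the stated noise
models. Real spectra add baseline drift, isotopologue peaks, adducts,
inner-filter effects, detector nonlinearity and correlated noise that the
generator deliberately omits; parameter recovery here is a necessary, not a
sufficient, check for field data.

## Numerical conventions

Gaussian noise throughout (ppm error, µmol error) with log-normal
intensities; deterministic outputs for a fixed seed (bit-identical reruns,
asserted in tests). Degenerate inputs are flagged rather than silently
propagated: empty peak lists (undefined assignment rate), flat spectra
(undefined slope ratio), zero CH4 windows, zero-area FTIR spectra and
single-moiety rank correlations all warn and return NaN/empty results.
Tables are written as UTF-8 CSV at 6 significant digits, except mass tables
at 10 to survive round trips at sub-ppm precision. Pipeline runs record the
package version and a SHA-256 config hash.

## Known limitations

- No isotope-pattern scoring, adduct handling beyond ±H⁺, or m/z
  recalibration; the ~1% fine-structure ambiguity at ≥ 0.5 ppm noise is
  irreducible within these constraints.
- The moiety database is a starter set; transformation profiles are only as
  meaningful as the supplied reference list.
- No PARAFAC or fluorescence indices beyond the four Coble ratios; no
  humification indices beyond the six FTIR bands.
- Headspace-only gas accounting understates total production where dissolved
  CO2 is substantial (high pH, large water volumes).
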