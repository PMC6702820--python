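# Methods

## The problem

*Polygonum multiflorum* Radix (a traditional Chinese medicinal root, He
Shou Wu) is steamed — classically "nine times" — to produce *Polygoni
multiflori* Radix Preaparata. The raw drug is hepatotoxic; proper steaming
reduces that toxicity, but incompletely processed material is hard to tell
apart from the finished product by appearance or by absolute component
contents, which vary strongly with growing region.

Steaming hydrolyses the anthraquinone glucosides (emodin-8-O-β-D-
glucopyranoside and physcion-8-O-β-D-glucopyranoside) into their aglycones
(emodin and physcion). The ratio

    F = (C_emodin-glc + C_physcion-glc) / (C_emodin + C_physcion)

is therefore a processing clock that cancels the absolute-level
variability. The decision rule implemented here is:

| rounded F        | label                    | meaning                    |
|------------------|--------------------------|----------------------------|
| F ≥ 1.0          | `crude`                  | unprocessed raw drug       |
| 0.6 < F < 1.0    | `incompletely_processed` | steamed, but not enough    |
| F ≤ 0.6          | `qualified`              | fully processed product    |

Classification operates on F rounded **half-up to two decimals**, matching
how the statistic is tabulated in practice (a sample printed as 0.60 counts
as qualified). The raw F is retained on every `FResult` for analysis. Both
boundaries are closed on the side of their band. A sample with glucosides
but no detectable aglycones has F = +∞ (crude); a sample with all four
contents zero raises an error rather than guessing.

## Single-marker quantification (QAMS)

Quantifying four analytes normally needs four reference standards. The
single-marker approach (quantitative analysis of multicomponents by a
single marker) predetermines, on control runs where all standards are
present, a relative correction factor per analyte *m* against the
reference *k* (emodin — by far the cheapest of the four standards):

    f_km = (W_k · A_m) / (W_m · A_k)

with *W* the injected concentration and *A* the peak area. Under a linear
detector response `A = r·W` this is the response-factor ratio `r_m / r_k`,
a property of analyte, wavelength and detector rather than of any single
run. Routine analysis then co-injects only the emodin standard:

    C_m = A_m · C_k,std / (f_km · A_k,std)        (single-marker)
    C_m = A_m · C_m,std / A_m,std                 (external standard)

Quantification is deliberately **single-point** (one control injection, one
sample injection), mirroring routine pharmacopoeial practice; the
calibration-curve module exists for method validation, not for routine
content computation. If the sample and control were injected at different
volumes, the ratio of injection volumes is applied. Contents convert to
mg per gram of drug via `C_m · V_extraction · dilution / mass` (default
extraction: 1 g refluxed in 50 mL methanol). Contents are carried
internally in mg·g⁻¹ at full precision; µg·g⁻¹ or rounded factors are
presentation-layer only.

Peaks are identified by **relative retention time** (RRT = rt / rt_emodin;
nominal values 1.00, 1.06, 0.47, 0.60) within a closed ±5 % window. A peak
matching two windows is flagged ambiguous and left unassigned; two peaks
competing for one analyte is an error, because silently picking one would
corrupt the quantification.

**Durability.** Factor robustness is summarised per analyte as mean and
RSD across condition groups (RSD = 100·sd/mean with the n−1 sample
standard deviation, the pharmacopoeial convention). Pass thresholds
default to ≤ 2 % across injection volumes (2–30 µL) and ≤ 3 % across
instrument/column combinations.

## Calibration and validation

Dilution bookkeeping is conservation of mass: each flask's concentration
is Σ(C_source · v_aliquot)/V_final, recipes may chain, and an overfull
flask is an error. `reference_control_series` reproduces the assay's
documented two-stock, seven-level series; the documented recipe contains
no emodin stock (although emodin is the reference analyte), so an emodin
stock can be passed in and is co-diluted with the same scheme.

Calibration curves are unweighted OLS of peak area on injected amount
(µg = mg·mL⁻¹ × µL), so one curve serves all injection volumes; `r` is the
Pearson correlation and no weighting is applied. LOD/LOQ default to the
signal-to-noise convention (3·noise/slope and 10·noise/slope; the ratio is
exactly 10/3) with a curve-based alternative (3.3·s_intercept/slope)
selectable — the published limits themselves are not recomputable without
the raw baseline noise and are not asserted anywhere.

Validation statistics follow the usual battery: precision on raw areas of
replicate injections (pass < 1 % RSD), stability on one solution
re-injected over 24 h (pass < 2 %), repeatability on computed contents of
parallel preparations, and spike recovery `100·(found − original)/added`
with the added amount taken as spike concentration × spiked volume
(evaporation to dryness treated as lossless). Per-portion masses are
explicit inputs, never inferred.

## Synthetic data

The generator gives every statistical claim a ground truth:

- **Chromatograms**: area = response_factor × injected amount, with
  multiplicative Gaussian area noise (default CV 1 %) and additive
  Gaussian retention-time jitter (default sd 0.02 min) — small enough by
  default that RRT assignment stays unambiguous. Default response factors
  are 1000/1090/440/490 area·µg⁻¹ so the factor ratios equal the
  assay's working values (1.09, 0.44, 0.49); retention centres
  (15.0/15.9/7.05/9.0 min) are arbitrary but fixed so the RRTs equal the
  nominal 1.06/0.47/0.60. Default true contents are a measured raw-drug
  profile (4.256/1.502/2.008/0.679 mg·g⁻¹). Output is bit-reproducible
  for a fixed seed.
- **Steaming kinetics**: first-order conversion,
  `C_glc(t) = C_glc(0)·e^(−kt)`,
  `C_agly(t) = C_agly(0)·e^(−loss·t) + y·C_glc(0)·(1 − e^(−kt))`.
  The real process is known only in direction (glucosides fall, aglycones
  rise, F saturates low); the exponential form is the simplest with those
  properties and is a configurable stand-in, **not** a mechanistic claim
  about processing chemistry. Defaults: k = 0.35 h⁻¹ and yield
  y = 0.63 (the aglycone/glucoside mass ratio — hydrolysis sheds one
  glucose), chosen once so a radix-like start (F ≈ 5) crosses the 0.6
  threshold around 8 h of steaming, the behaviour observed in practice;
  loss = 0 keeps F strictly decreasing. With y = 1 and loss = 0 each
  glucoside/aglycone pair conserves total mass exactly.
- **Cohorts**: per-sample F is drawn from per-type band mixtures (crude
  drug uniform on [1, 10]; declared processed product ~83 % qualified,
  ~8 % incomplete, ~9 % crude-like, the proportions of the market survey),
  then realised as four contents around a lognormal aglycone total split
  3:1 emodin:physcion. Band ranges avoid the rounding boundaries so drawn
  labels are unambiguous.

What the generator does **not** emulate: gradient elution and peak-shape
effects (co-elution, tailing, detector saturation), between-batch matrix
effects, heteroscedastic detector noise, and any real covariance between
the four contents beyond the F construction. Passing tests therefore
demonstrate the correctness of the arithmetic, the estimators and the
decision rule — not the chromatographic ruggedness of the wet-lab method.

## Numerical choices

- Half-up decimal rounding (via `decimal` on the float's shortest repr)
  for every presented value; binary-float ties never flip a band.
- RRT window boundary: closed, with a 1e-12 relative epsilon so an exactly
  boundary-placed peak is accepted regardless of float representation.
- The steaming-series monotonicity check is advisory (a warning, not an
  error), with a default jitter allowance of 15 % per step: real series
  show small late-time upticks (e.g. 0.09 → 0.10) that carry no signal.
- OLS via `scipy.stats.linregress`; rate recovery by log-linear least
  squares, exact on noiseless series.
- Degenerate inputs fail loudly: 0/0 F, zero-variance calibration x,
  single-group durability, zero reference area.

## Known limitations

- Recomputing F from printed three-decimal contents does not always
  reproduce a published F computed on unrounded contents; on the packaged
  172-row market table, 165 rows agree at ±0.01 and the 7 exceptions (all
  with small aglycone denominators) are enumerated in the test suite.
- Single-reference design: the reference peak is obligatory in every run;
  there is no multi-marker fallback.
- The kinetics module fits a single first-order rate; it does not model
  multi-step hydrolysis or moisture/temperature dependence.
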