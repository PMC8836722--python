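# Methods

## Scope

`icpkit` implements the analysis layer of a multiparameter ICP-monitoring
prognosis study: index computation from 3-second trend data in 1-hour
segments, patient-level aggregation, two-group comparison statistics, and
ROC evaluation of each index as a predictor of poor outcome. It operates on
trend channels only — ICP pulse amplitude (AMP) arrives as an exported
monitor channel, since 3-second trend sampling cannot resolve cardiac
beats; no beat-level waveform processing is attempted.

## Index definitions and conventions

**Segmentation.** A recording is split into consecutive non-overlapping
segments of `floor(3600·h / dt)` samples (default 1 h at dt = 3 s → 1200
samples). A trailing partial segment is kept and flagged. Dropouts are
flagged invalid rather than deleted, so segment arithmetic stays
index-based. A segment must be ≥ 50% valid (configurable) for its mean ICP
and CPP to be defined; undefined values propagate as missing, never as 0.

**Mean ICP, CPP.** Arithmetic means over valid samples; CPP is the mean of
MAP − ICP over the same samples, so the identity
`mean_cpp = mean_map − mean_icp` holds to machine precision.

**PRx.** Pearson correlation of (MAP, ICP) sample pairs in sliding windows
of 300 s stepped by 60 s, averaged over the segment's qualifying windows.
A window qualifies if ≥ 75% of its samples are valid and both channels have
non-zero variance — a zero-variance window yields *no* correlation rather
than 0, since 0 would assert "no reactivity" from no information. The
window/step lengths follow the established neuromonitoring convention and
are configurable; `window_s = 3600` recovers a single correlation per hour.
The correlation is applied to the 3-s samples directly (no 10-s
re-averaging: the input is already a trend, not a waveform).

**RAP.** The same sliding-correlation machinery applied to (AMP, ICP), with
240-s windows (≈ the conventional number of multi-second averages). A
series without an AMP channel raises a distinct error; it does not produce
an undefined index silently.

**DICP (pressure-time dose).** Each valid sample represents its own
sampling interval, giving `dt · Σ max(0, ICP − threshold)` over valid
samples (threshold 20 mmHg by default, the recommended treatment threshold
for this population). Within a run of consecutive valid samples this is
identical to trapezoidal integration of the supra-threshold excess plus a
half-interval constant extension at the two run ends. The rule was chosen
because it simultaneously (i) never bridges across invalid gaps — no
pressure is invented during dropouts, each valid run is integrated
separately; (ii) is exactly additive over any partition of the samples;
(iii) gives the exact closed forms a full segment should have (constant
25 mmHg for 1 h → exactly 5 mmHg·h; at-threshold → 0); and (iv) is monotone
non-increasing in the threshold. A pure between-sample trapezoid spans only
(n−1)·dt of an n-sample hour and misses (iii).

**Aggregation.** Patient-level mean ICP, CPP, PRx and RAP are means over
the segments where the respective index is defined. Patient-level DICP is
the monitoring-period **total** (sum of segment integrals) — the scale on
which 3-day doses of hundreds of mmHg·h arise; a partial segment
contributes exactly its own area. A patient with no defined segment at all
is excluded, with the reason recorded in the run log.

**CPPopt.** Segments are binned by mean CPP (5-mmHg bins); bins with ≥ 2
segments enter a quadratic least-squares fit of mean PRx against bin
centre, requiring ≥ 4 populated bins. The vertex abscissa is reported only
if the parabola opens upward and the vertex lies inside the observed CPP
range; otherwise the estimate is undefined with a reason code. The curve is
fitted against CPP (the perfusion variable the optimum is defined over),
which is the convention of the CPPopt literature.

## Synthetic cohort generator

The generator produces the minimal signal structure that makes all five
indices independently steerable:

- MAP = baseline + A·sin(2πt/P + φ) + noise, with P = 60 s by default
  (Lundberg-B band, 30–120 s) and A = 4 mmHg;
- ICP = baseline + g·(MAP slow wave) + independent B-wave (amplitude
  2 mmHg, period 100 s) + noise. The reactivity gain g sets the sign and
  size of the MAP–ICP correlation and hence PRx;
- AMP = a₀·exp(E·(ICP − baseline)) + noise below the critical ICP
  (steep-zone compensation, RAP > 0), declining linearly above it with the
  mirrored slope (exhausted compensation, RAP < 0), then clipped at 0;
- a configured fraction of samples (exactly `round(f·n)`) is flagged
  invalid at random positions.

All randomness flows from one integer seed; identical config ⇒ identical
series. Per-patient seeds are an arithmetic fold
`(master·1000003 + j·10007 + 12345) mod 2³¹` of the master seed and the
patient index, stable across runs.

**Calibration.** Cohort defaults reproduce a published 53-patient HICH
case-mix: group sizes 27 (good prognosis, GOS IV–V) and 26 (poor, GOS
I–III); per-patient ICP baselines drawn from N(10.12, 4.37²) and
N(27.68, 13.17²) mmHg, CPP from N(73.65, 8.27²) and N(55.88, 14.68²), and
PRx/RAP targets from N(0.05, 0.098²)/N(0.14, 0.10²) and
N(0.34, 0.12²)/N(0.37, 0.12²). Within a correlation window the model is a
sum of independent components, so the expected PRx for a gain g has the
closed form `g·σ²_sw / √((σ²_sw+σ²_map)(g²σ²_sw + σ²_bw + σ²_icp))`, which
is inverted per patient to map a drawn PRx target to a gain; likewise the
linearised AMP relation gives `RAP = k/√(k²+σ²_amp)` with `k = E·a₀·σ_icp`,
inverted to map a RAP target to an elastance. Targets are clipped to
(−0.85, 0.85) and (0.01, 0.90); ICP baselines to ≥ 3 mmHg and CPP draws to
[20, 130] mmHg. The group templates place the critical ICP at 60 mmHg so
the poor group sits in the steep (RAP > 0) zone as observed clinically;
regime studies lower it explicitly. Covariates (age, sex, GCS 4–9,
haematoma volume clipped to the 20–50 mL inclusion window, GOS) follow the
published group distributions.

**What the generator does not emulate.** Treatment feedback (osmotherapy,
repeat surgery), circadian structure, plateau waves, correlated artifact
bursts, non-stationary autoregulation, and the true skew of the DICP
distribution (only medians/IQRs of the study are known; the simulated
per-patient dose skew is a by-product of the ICP-baseline spread and is not
claimed to match the study's dispersion). Passing cohort-level tests
therefore demonstrates correctness and calibration of the *analysis*, not
fidelity of the generator to any particular patient population.

## Statistics

- **Pooled t**: equal-variance two-sample t with df = n₁+n₂−2, computable
  from summaries (mean, SD, n) or raw samples with identical results. The
  equal-variance form (not Welch) is used because it is the form that
  reproduces the published table's statistics from its printed summaries.
- **Mann–Whitney U**: both pair-count orientations are reported
  (`u_less`, `u_greater`) plus their minimum; p from the normal
  approximation with tie-corrected variance and continuity correction
  (group sizes ~26 are far beyond exact-enumeration need; an O(n²)
  enumeration oracle backs the tests).
- **Chi-square**: uncorrected Pearson on the 2×2 sex table (the form that
  reproduces the published 0.018); a zero marginal is an error.
- **Test assignment** per variable is explicit configuration (t for age,
  volume and the four index means; Mann–Whitney for GCS and DICP;
  chi-square for sex), mirroring fixed study choices rather than an
  automatic normality screen.
- **ROC**: empirical curve over all distinct thresholds with declared
  orientation per index (never auto-flipped); trapezoidal AUC, which equals
  the tie-adjusted U/(n₁·n₂) identically. CIs by DeLong's method (default)
  or Hanley–McNeil, truncated to [0, 1]. In small samples with AUC near 1
  the untransformed DeLong interval is known to undercover (measured ≈ 89%
  at nominal 95% for a true AUC of 0.92 with n = 26/27); this is a property
  of the standard method, retained deliberately for comparability with
  common software defaults.

## Problem sizes used in the test suite

Unit and property tests run on 1-hour, 1200-sample segments. The
cohort-level Monte-Carlo checks simulate 53-patient cohorts at 6 h per
patient — the per-patient index estimates are already stable at that length
(≥ 300 correlation windows per patient) and the group-level contrasts are
duration-invariant by construction — with 100 master seeds for the
calibrated-cohort power check and 300 for the null-cohort type-I check
(a ~5% level must be estimated with Monte-Carlo error well under the 10%
bound). The acceptance script runs the full 3-day, 53-patient design.

## Known limitations

- PRx/RAP window conventions are configurable but the study's own
  sub-windowing (if any) is unknown; one-correlation-per-hour is available
  via `window_s = 3600`.
- The patient-level RAP distribution in the good group carries a small
  point mass from target clipping at 0.01, which makes the pooled t on RAP
  slightly liberal (~7% at nominal 5%) at n ≈ 27 in null simulations.
- CPPopt requires ≥ 4 populated CPP bins; stable recordings with a narrow
  CPP range legitimately yield no estimate.
- No multivariable modelling, no multiple-testing adjustment, no optimal
  cut-point (Youden) reporting: the downstream study design reports none.
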