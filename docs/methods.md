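# Methods

## Model structure and assumptions

The simulator treats bark-beetle development as a purely
temperature-driven, stage-free accumulation process: a brood's state is a
single scalar, the relative thermal sum Tsum ∈ [0, ∞), and every daily step
adds BTeff/K where BTeff is the day's effective bark temperature and
K = 557 degree-days the requirement for complete egg-to-adult development.
Stages (egg, larva, pupa, teneral adult, emerged adult) are read off Tsum
after the fact; they carry no stage-specific thresholds or mortality. The
model therefore assumes (i) development rate depends on temperature only,
(ii) one parameter set describes total development, and (iii) populations
at a site are synchronous — a brood is a point in Tsum, not a distribution.

Temperatures pass through two fixed affine corrections (open land → forest
stand → phloem) whose coefficients are taken as given; refitting them is
out of scope. The three scenarios MIN/AVG/MAX drive development with the
daily minimum/mean/maximum bark temperature respectively and bracket the
within-day uncertainty; onset detection is scenario-independent because it
reads the raw daily maximum air temperature.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `swarm_dd` | 53.0 | dd | cumulative Σmax(0, I_max−8.3) for spring swarming |
| `infest_dd` | 155.6 | dd | same sum for onset of infestation |
| `flight_t` | 14.5 | °C | daily I_max gate for any flight event |
| `daylength_gate` | 14.5 | h | photoperiod below which no new brood starts |
| `k_total` | 557 | dd | thermal sum for complete development |
| `hibernation_min` | 0.6 | — | final Tsum needed to survive winter / be counted |
| `start_month_day` | 7 Mar | — | first day of degree-day accumulation (calibratable) |
| `end_month_day` | 31 Oct | — | end of season; broods are frozen and evaluated here |
| `dev.dt_l / t_o / dt_u` | 8.3 / 30.4 / 38.9 | °C | development-rate thresholds |
| `dev.alpha/beta/gamma/t_max_nl` | see code | — | exponential-branch constants |
| `max_filial`, `max_sister` | 3, 3 | — | brood caps |
| `stage_bounds` | 0.1, 0.5, 0.6, 1.0 | — | Tsum breakpoints between stages |
| `horizon_angle` | 0.0 | deg | sun elevation defining sunrise (see below) |

## Numerical and convention choices

**Inequalities exactly as printed.** Degree-day onset thresholds and the
day-length gate are non-strict (≥); the flight-temperature gate and the
brood-initiation thresholds on Tsum_F1 are strict (>). No epsilons are
added anywhere; comparisons are plain float64. The acceptance probes locate
every one of these boundaries by bisection, which confirms the side each
boundary point falls on.

**Onset semantics.** An onset fires on the first day on which the
cumulative condition and the same-day gate hold simultaneously; a threshold
crossing on a cold day does not trigger retroactively. Daily degree-day
increments are truncated at zero so cold days never erase accumulated sum.
The onset day itself is included in a brood's accumulation.

**The optimum discontinuity.** The development-rate function jumps from
22.1 dd (linear branch, which owns BT = 30.4 °C) to ≈ 21.674 dd just above
the optimum. The jump is kept as published; smoothing it would change
every warm-season thermal sum. The exponential branch evaluated just below
the upper threshold is ≈ +0.0137 dd (near-continuous); it is clamped at 0
from below as a guard against parameter edits driving it negative —
development rates cannot be negative.

**Third filial generation.** F3 starts at Tsum_F1 > 2, read on the *first*
generation's thermal sum, not at Tsum_F2 > 1. The two differ when F2's
start was delayed by a gate; the published rule is implemented literally.

**Diapause gate scope.** Day length gates only the *initiation* of broods.
A brood started in July continues accumulating into October even when days
are short — the gate appears only in onset conditions.

**Day length.** Computed with the Cooper declination approximation and the
geometric sunrise formula (sun centre on the horizon, no refraction), with
the hour-angle argument clamped for polar day/night. The convention
matters: at 46° N the 14.5 h threshold crossing moves by roughly a day
between the geometric and civil conventions, so `horizon_angle` is exposed
(−0.83° reproduces civil sunrise) with the geometric convention as the
default — it is the assumption-free choice given no statement to the
contrary. Leap years are handled through calendar dates; the 365-day
denominator in the declination costs ≪ 0.1 h.

**Stage intervals.** The published stage ranges share endpoints, so the
implementation uses half-open intervals with each interior breakpoint owned
by the later stage, and labels Tsum ≥ 1.0 "emerged adult". This is a pure
tie-break; only the four breakpoint values are substantive.

**Re-emergence and voltinism reporting.** The S1 onset date doubles as the
parental re-emergence date (re-emerged parents are what lay the sister
brood). Filial and sister counts are reported separately; no 0.5-weighted
combined index is formed, since any such weighting is a presentation choice
that the separate counts preserve.

**Calibration objective.** The combined objective is the unweighted mean of
the swarming MAE and the infestation MAE. Site-years with an absent
prediction are excluded from the mean but counted, and a candidate
predicting fewer than 90 % of its pairs is disqualified — otherwise a very
late start date that never predicts anything could score an empty "perfect"
MAE. Ties are broken toward the latest candidate, matching the procedure's
definition as the *latest* workable date. The default grid searches every
day from 1 February to 30 April.

## Synthetic weather

The generator produces a seasonal sinusoid (mean + amplitude·cos, peak at
`phase_day`) with Gaussian daily noise on the mean and half-normal noise
applied *outward* from the diurnal envelope, so min ≤ mean ≤ max holds by
construction for every draw — simpler than clipping, at the cost of the
min/max means being biased outward by E|η|. Defaults (annual mean 9.5 °C,
amplitude 10 °C, peak day 200, diurnal range 9 °C, noise sd 2 °C, latitude
46.37° N) describe a sub-Alpine Central European site in the beetle's
outbreak range. Grids add a per-row annual-mean offset (`lapse`) and a
seeded host mask; cell (0, 0) of a 1×1 grid reproduces the point generator
bit-for-bit.

What the generator deliberately lacks: day-to-day autocorrelation, weather
fronts, elevation effects within a cell, and any coupling between noise and
season. Tests passing on this weather therefore demonstrate the *model
mechanics* (onset logic, accumulation, gating, counting) and the pipeline's
internal consistency — not predictive skill on real meteorology, which
requires validation against observed onset data via the calibration module.

## Problem sizes

The test suite and the acceptance script run at the sizes the checks need
and no more: bisections to tolerances of 1e-4…1e-9 (25–47 iterations), a
290 001-point branch-switch scan, 50 synthetic years against the
brute-force daily oracle, 200 years for the ordering properties, 15
site-years × 89 candidate dates for calibration recovery, and a 10×10 grid
(≈ 80 unmasked cells) for grid/point consistency. The whole suite completes
in well under a minute on one core.

## Known limitations

No population abundance, mortality, dispersal or risk index; no winter
development or multi-year carryover of partially developed broods (broods
are evaluated and discarded at 31 October); a single parameter set for all
stages; deterministic single-point broods rather than phenological
distributions. Latitude for the day-length gate is taken from the raster
geotransform only for geographic CRSs — projected grids need an explicit
per-run latitude.
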