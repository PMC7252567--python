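# Methods

`tierexpo` computes five nested ("tiered") daily exposure metrics for
ambient PM2.5, elemental carbon (EC), nitrogen oxides (NOx) and carbon
monoxide (CO) for individual participants of a panel study, each metric
split into background, on-road and total source components. This note
documents the models, the assumptions behind them, the parameters that
matter, and the choices made where the design was genuinely open.

## The five tiers

For each participant-day (a 24-h window from 8 am to 8 am local time),
pollutant and component:

1. **Home outdoor concentration** `C_out_home` — the hourly outdoor
   concentration field evaluated at the centroid nearest the home,
   averaged over 24 h. The field itself (e.g. a dispersion + kriging
   product, or this package's synthetic generator) is an input, not
   something this package models.
2. **Home indoor concentration** `C_in_home` — a single-compartment
   mass balance driven by the hourly air exchange rate (AER):

       dC_in/dt = AER · P · C_out − (AER + k_r) · C_in

   with `P` the envelope penetration coefficient and `k_r` the
   first-order indoor removal rate. *Erratum note:* the source
   formulation of this balance is sometimes printed with the outdoor
   concentration in the loss term; conservation of mass requires the
   indoor concentration there, and that standard form is what we
   implement.
3. **Personal outdoor concentration** `C_out_personal` — each 5-s GPS
   sample matched in time to the enclosing field hour and in space to
   the nearest centroid (great-circle distance), averaged over the
   day's 17,280 ticks.
4. **Exposure** `E` — a microenvironment (ME)-weighted blend at each
   tick, using the five-class ME view (indoors at home/work/other,
   in-vehicle, outdoors):

       E = ME_in_home·C_in_home
         + [(ME_in_work + ME_in_other)·F_inf_other_bldg
            + ME_in_vehicle·F_inf_vehicle + ME_out]·C_out_personal

   `F_inf_other_bldg` and `F_inf_vehicle` are single-number
   infiltration factors for non-home buildings and vehicles.
5. **Inhaled dose** `D` — per tick and per seven-class ME,
   `D_i = E_i · MV · AT / BSA`, with `MV` the minute ventilation
   (m³/min), `AT` the tick length in minutes and `BSA` the DuBois body
   surface area `0.007184·BH^0.725·BW^0.425` (BH cm, BW kg). The daily
   dose is the sum of the 17,280 increments; `AT` is 5/60 min exactly
   (not a rounded 0.083).

Every stage is linear in concentration, so the background and on-road
records sum to the total record field-by-field; this additivity is
enforced as an invariant throughout and checked end-to-end in tests.

### Pollutant parameters

Literature-derived defaults, compiled into an immutable registry and
overridable from a TOML `[pollutants.<name>]` section:

| pollutant | P    | k_r (1/h) | F_inf_other_bldg | F_inf_vehicle |
|-----------|------|-----------|------------------|---------------|
| PM2.5     | 0.84 | 0.21      | 0.64             | 0.44          |
| EC        | 0.98 | 0.29      | 0.59             | 0.44          |
| NOx       | 1.00 | 0.5       | 1.00             | 0.80          |
| CO        | 1.00 | 0         | 1.00             | 1.00          |

CO's `k_r = 0` is taken literally: ambient CO is neither attenuated
indoors nor removed, so under a constant field every tier concentration
coincides — a useful end-to-end identity that the acceptance tests
exploit.

## Air exchange rate (extended LBL model)

Hourly AER = `Q_total / V` with `Q_total = (Q_leak² + Q_nat² +
Q_mech²)^0.5`:

* `Q_leak = A_leak · (k_s·|T_in − T_out| + k_w·U²)^0.5` (evaluated in
  m³/s, reported in m³/h). `A_leak` is the effective leakage area (m²),
  `k_s` the stack coefficient ((m/s)²/K), `k_w` the dimensionless wind
  coefficient, `U` wind speed (m/s).
* `Q_nat` — orifice flow through the reported openable window/door area
  with discharge coefficient 0.6, driven by the same stack/wind
  velocity scale, active only on days the questionnaire reports open
  windows or doors.
* `Q_mech` — the rated window-fan flow on days the fan is reported on.

`k_s` defaults by number of stories (0.0145/0.0290/0.0435 (m/s)²/K for
1/2/3 stories) and `k_w` by stories × wind-shielding class, the classic
LBL lookup convention converted to SI. These built-in coefficient
tables and the orifice form of `Q_nat` are this package's own
documented stand-ins for building-specific calibration data, not
reproductions of any particular study's supplementary tables; every
number is a constructor argument.

Indoor temperature is held at the daily questionnaire value; each
hour's AER uses that hour's weather. On the five lag days before a
questionnaire, its answers are copied backwards and the records flagged
imputed.

## Infiltration integration

With `C_out` and AER piecewise-constant over each hour, the mass
balance has the exact update

    C(t+Δ) = C_ss + (C(0) − C_ss)·exp(−(AER+k_r)Δ),
    C_ss = AER·P·C_out/(AER+k_r),

so the hourly integrator is exact and unconditionally stable (no Euler
step-size error). The series is initialized at the first hour's steady
state rather than zero, so an arbitrary spin-up transient never
contaminates the first daily average; when `AER + k_r = 0` (CO in a
sealed house) the concentration holds its initial value `P·C_out(0)`.
Tests verify the integrator against a brute-force 1-s forward-Euler
oracle to within 0.1% of the daily mean.

## Microenvironment classification

Each 5-s GPS sample is labeled with one of seven MEs via a small
decision tree: sustained speed above 10 km/h for ≥30 s ⇒ in-vehicle;
otherwise place membership by radius (40 m default) around the geocoded
home/work centers, nearest wins, everything else "other"; then indoor
vs outdoor by fix quality (no fix, or PDOP > 4 ⇒ indoors, since
buildings attenuate satellite reception); finally a 60-s majority-vote
dwell smoothing in which the current label wins ties. Samples with no
data inherit the previous label (a leading gap back-fills). All
thresholds are configuration.

This decision tree is a deliberately compact formulation of the
GPS-classifier idea — speed, place geometry, fix quality, dwell
smoothing — not a reimplementation of any proprietary classifier; the
synthetic-data experiments below quantify what it recovers under the
noise model we generate.

Lag days copy the observed day's labels; on weekend lag days work
labels become home labels. We apply the substitution to both the indoor
and outdoor work labels so that the label copy stays consistent with
the geolocation copy (which relocates all work-radius samples to home).

## Activity and ventilation

At each 5-s tick the past 60 s of 1-s accelerometer counts are summed
(cpm); the day's first 59 s pad with zeros, biasing only the first
ticks toward sedentary. PAL cut-points: sedentary < 100 ≤ light < 1535
≤ moderate < 3962 ≤ vigorous (device-specific published thresholds;
boundary values belong to the upper class). Ticks whose ME is
in-vehicle are forced sedentary, because the accelerometer senses
vehicle vibration while the occupant sits. Minute ventilation is
`NMV(PAL, age band, sex) · BW / 1000` m³/min from a 4 PAL × 14 age
band × 2 sex table. The shipped default table contains *synthetic
placeholder medians* with realistic structure (nondecreasing in PAL,
declining with adult age); studies with access to published NMV medians
should load them via `NmvTable`/CSV. NMV is looked up per age band, not
interpolated.

## Synthetic study generator

The generator emulates the data streams of a repeated-measures panel:
15 adults, four visit-weeks each with two consecutive clinic weekdays
(120 clinic participant-days), five lag days per clinic day (720
scheduled participant-days), spread over ~25 months; a ~25 × 30 km
domain with a 0.03° centroid grid (108 centroids) and two emitting
roads.

* **Background fields**: per-pollutant mean × a smooth spatially
  correlated surface (coarse random grid, bilinear interpolation) × a
  diurnal cycle × a lognormal day-to-day synoptic factor. Means
  (µg/m³): PM2.5 10, EC 0.5, NOx 20, CO 300.
* **On-road fields**: exponential distance decay (length 250 m) from
  the road polylines × a double-peaked traffic diurnal × a day factor.
  Road-edge peaks (µg/m³): PM2.5 3, EC 2.5, NOx 80, CO 120 — chosen so
  the on-road share exceeds background near roads for EC and NOx and
  not for PM2.5 and CO, the qualitative regime of near-road gradients.
  Total = background + on-road exactly, by construction.
* **Tracks**: day plans (home → commute → work → lunch walk → work →
  commute → outdoor time → home on workdays; home/errand templates
  otherwise) realized as 5-s positions with meters-scale noise.
  Indoors, fixes drop out with probability 0.5 and surviving fixes
  carry lognormally inflated PDOP (median 6); outdoors fixes are
  nearly always valid with median PDOP 2 — the degradation pattern a
  fix-quality classifier keys on.
* **Accelerometer**: 1-s Poisson counts with PAL-dependent means
  (0.8/8/40/80 counts/s for sedentary/light/moderate/vigorous);
  in-vehicle spans emit light-level counts so the sedentary override
  has something to correct.
* **Weather and questionnaires**: sinusoidal seasonal + diurnal
  temperature with noise, folded-normal wind; window/fan behavior
  seasonal.

Everything derives from the scenario seed through keyed RNG streams, so
any date or participant-day regenerates bit-identically in isolation.

What the generator does **not** emulate: dispersion physics or kriging
(fields are statistical stand-ins with the right character, not
transport models), multi-stop trips, transit modes other than driving,
indoor pollutant sources, GPS multipath structure, device-specific
count spectra. Passing tests therefore demonstrate the pipeline's
internal correctness (linearity, conservation, classification under
the stated noise model) — not field accuracy against real loggers.

## Numerical choices and degenerate inputs

* Exposure ticks use the 5-class ME; the dose breakdown uses the
  7-class ME, with the hourly indoor series held piecewise-constant
  across each hour's 720 ticks.
* Nearest-centroid matching uses the haversine distance on WGS84
  (county-scale error < 0.1%); ties break to the lowest centroid id.
  Hour matching is floor(t), piecewise-constant, no interpolation
  between hours or centroids.
* The steady-state indoor/outdoor ratio is undefined at AER = k_r = 0
  and raises rather than guessing.
* Day windows are half-open [08:00, 08:00 + 24 h) local clock time;
  timestamps are serialized as naive local ISO-8601 throughout, since
  the whole pipeline is defined in a single study-local clock.
* Weather gaps, field coverage gaps, misaligned series and non-one-hot
  ME indicators raise typed errors naming the offending span.
* Scheduled participant-days are counted with multiplicity when lag
  windows overlap (consecutive clinic days share lag days); unique
  days can be recovered from the schedule.

## Known limitations

* The AER coefficient defaults and the natural-ventilation orifice
  model are physically motivated stand-ins; homes with measured
  leakage/tracer data should calibrate `HomeModel` per house.
* The default NMV table is synthetic (see above).
* Buildings are radius-buffered points; footprint polygons would
  sharpen place membership for large or irregular buildings.
* One concentration value per centroid-hour: sub-hourly plumes and
  within-block gradients are invisible to Tier 3.
* No non-ambient (indoor-source) pollution is modeled anywhere; the
  metrics are ambient-only by design.
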