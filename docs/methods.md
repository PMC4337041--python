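# Methods

`lvfast` quantifies left-ventricular (LV) function from short-axis cine
cardiac MRI with no user interaction.  This note describes the model and
procedure the package implements, the parameters that matter, what the
synthetic phantom does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Problem setting

A short-axis cine study is a 4D array `(slice, phase, row, col)`: a stack of
8–16 slices spanning the LV from the mitral-valve level (base) to the apex,
each reconstructed at 20–28 cardiac phases.  On SSFP images the blood pool
is bright and the myocardium dark, so the endocardial boundary is a strong
intensity edge — except at the two ends of the stack.  The basal slice is
only partially encircled by myocardium (the outflow tract opens toward the
aortic root), and the apical cavity is small and poorly resolved.  Those
two ends are exactly where naive per-frame segmentation fails, and where a
human operator normally intervenes.  The package's organising idea is that
the cavity area surface `A(p, s)` over phase `p` and slice `s` is smooth
wherever segmentation succeeded, so abrupt departures from the
mid-ventricular band localise the failures and bracket the true apical and
basal extent automatically.

Conventions: slice 0 is the most basal acquired slice; phase 0 is the first
reconstructed phase (nominal end diastole); phases are cyclic; areas are in
pixels internally and converted to mL only by the volumetry step.

## Pipeline

**1. Localization.**  The mid-ventricular slice `ms = n_slices // 2` is
differenced between two phases (defaults 0 and 7, i.e. nominal end diastole
and nominal end systole of a 20-phase reconstruction; configurable).  The LV
is the roundest structure undergoing the most motion, so the centre of the
strongest circle in a circular Hough transform of the difference image's
edge map seeds the segmentation.  Edges are Sobel gradient magnitude above
the Otsu level (the choice of edge operator was open; a gradient edge map
makes the accumulator peak sharp and scale-free).  The radius range defaults
to 8–40 px at 1.4 mm spacing, rescaled by the actual pixel spacing — LV
cavity radii of roughly 1–6 cm.  Accumulator ties are broken
deterministically: smallest radius, then smallest row, then column.

**2. Region growing.**  Each frame is segmented by iterative
decreasing-threshold region growing from its seed.  With `I0` the mean
intensity of the seed's 3×3 neighbourhood, the region at threshold fraction
`t` is the set of pixels 4-connected to the seed with intensity ≥ `t·I0`;
`t` starts at 0.95 and decreases in steps of 0.05.  Two stopping rules:

* *plateau*: if the pixels added by a step have mean intensity below
  `0.6·I0`, the region has reached the dark myocardial wall — keep the
  previous region;
* *leak*: if a step inflates the area by more than a factor 2 **and** the
  added pixels are dimmer than `0.85·I0`, the region has escaped through a
  narrow partial-volume bridge into a neighbouring structure — keep the
  pre-leak region and flag the frame `leaked`.

The intensity condition on the leak rule matters on noisy data: the first
thresholds sit inside the blood-pool noise band, so the seed component may
start fragmented and consolidate in one large step; consolidation adds
pixels near blood intensity, whereas a genuine leak adds dimmer
partial-volume tissue.  A leak into an equally bright structure (the aortic
root at the base) is deliberately *not* caught here — it lands in the area
map, where the continuity stage detects it, which is the division of labour
the whole method is built on.  Holes in the region (papillary muscles
surrounded by blood) are filled, matching the clinical convention of
counting them in the cavity volume.  All constants are exposed in
`GrowConfig`.

Growth is anchored at `ms`: all phases of the middle slice are grown from
the Hough seed, then slices are processed outward in both directions, each
frame seeded by the blood-pool centre of mass of the adjacent completed
slice at the same phase (snapped to the nearest mask pixel only when the
centroid falls clear of the mask, as in crescent-shaped pools).

**3. Jump classification.**  For each phase, sweeping outward from `ms`,
each cell is compared with its already-accepted neighbour one slice closer
to `ms`: the area ratio `J` and the centre-of-mass displacement `D`.  A cell
with `J > 2.5` or `D > 6` px is a *jump image*, and everything at and
beyond the first jump slice of that phase is unreliable.  The thresholds are
the empirical values of the original method (fixed on held-out clinical
cases); both are configurable in `JumpParams`.  The reference is always the
neighbour toward the mid-ventricle because that is the trusted anchor; the
source method did not fix a direction.  Temporal adjacency (cyclic over the
cycle) corroborates the spatial rule: a slice whose temporal comparison
fails for at least half of its phases is flagged wholesale.  The temporal
count runs over *all* phases of the slice, not only the spatially accepted
ones — this makes the flagged set provably monotone as the thresholds
tighten, which is also asserted as a property test.

**4. Apical repair.**  Flagged apical cells are replaced by estimates, not
re-segmented (the cavity there is a few pixels across).  For a jump cell
`(p, s)` with at least one reliable phase at slice `s`, the phase-scaled
estimate transfers the area from the nearest reliable phase `q` (cyclic
distance, earlier phase on ties):

    A'(p, s) = A(q, s) · Σᵢ A(p, i) / Σᵢ A(q, i),   i = ms … s−1,

i.e. scaled by the volume ratio of the reliable mid-to-apical section
between the two phases; it reduces to the identity when `p = q`.  When the
slice with jumps still has at least 90% reliable phases, the next slice
toward the apex is additionally extended by cone interpolation

    A' = (2·√A₁ − √A₂)²,

the unique area extrapolation in which the equivalent circular radius
tapers linearly (a cone's cross-sections), clamped at zero past the apex;
`A₁`, `A₂` are the areas one and two slices closer to the base.  The
printed form of this rule in the source literature mixes units (it contains
a raw area product); the radius-linear reading is the only dimensionally
consistent one and is what is implemented.  The apical extent per phase is
the last slice with positive corrected area.

**5. Basal detection.**  By convention the most basal LV slice has at least
50% of its circumference in contact with myocardium.  The first basal jump
slice of each phase is interrogated against the last reliable slice:

* both masks are smoothed (morphological closing then opening, disk of
  radius 3 px, in that order);
* each is mapped to polar coordinates around the reliable slice's blood-pool
  centre: for every 1° ray, marched in 0.5 px steps, the radius of the first
  background run of length ≥ 2 px is the *apparent myocardial border* (short
  noise gaps are skipped), and the two pixels immediately beyond it are
  *apparent myocardial points*;
* the *zero angle* is the middle of the longest contiguous angular run where
  the two borders agree to within `D` px (`D` is the same 6-px displacement
  threshold as the jump rule — the source method lists a single `D`);
  scanning both ways from it, the *termination angles* are the first bins
  where the candidate's border exceeds the reference by more than `D` px;
* the slice still contains LV iff the covered sector (the arc through the
  zero angle) spans ≥ 180° and the mean intensity of its apparent myocardial
  points is within 30% of the reference slice's — a brighter rim means the
  candidate is atrium or aorta, not LV;
* if it contains LV, the cavity is closed by the straight chord joining the
  two termination points (clipping the grown region to the zero-angle side),
  as a clinician draws the basal boundary across the valve plane.  Otherwise
  the slice is excluded and the base starts one slice higher.

**6. Volumetry.**  Disk summation: `V(p) = Σₛ A(p, s) · pixel-area ·
slice-spacing / 1000` mL over the detected basal-to-apical range, with the
slice spacing equal to thickness plus gap (10 mm in the emulated protocol) —
the standard choice when gaps exist, so no inter-slice interpolation is
applied.  End diastole and end systole are the maximum and minimum of the
measured volume curve (earliest phase on ties), not the nominal seeding
phases; `EF = 100·(EDV − ESV)/EDV`.  A paired-difference utility
(mean, SD, two-sided paired-t p) is provided for users validating against
their own manual tracings.

## The phantom

The generator exists so every stage is testable without any acquisition.
The LV cavity is a half-ellipsoid of revolution truncated at the basal
plane: at depth `z` the radius is `r(z, p) = R(p)·√(1 − (z/L)²)` with `L`
spanning the acquired slices.  Contraction is purely radial with
`R(p) = R_ED·√(1 − EF·c(p))`, which makes the analytic volume exactly
`EDV·(1 − EF·c(p))` — the EDV and EF targets are met by construction, up to
voxelisation.  The contraction fraction `c(p)` is a raised cosine over the
first third of the cycle (systole; end systole thus falls near the
conventional eighth phase of a 20-phase study) followed by a rapid
raised-cosine early filling to a diastasis level of 0.12 and a slow linear
return that wraps smoothly to `c(0) = 0`.  The exact curve shape is a free
choice — no source prescribes one — selected to give a physiologic-looking
filling curve with distinct early-filling and diastasis segments.

A myocardial shell of fixed 8 mm thickness surrounds the cavity.  On the
basal slice(s), an angular sector (default 150°) of the shell is replaced by
blood-intensity tissue extending radially outward — the outflow tract — and
optionally connects to a circular blood-bright distractor blob (aortic
root/atrium).  Defaults emulate the acquisition the pipeline targets:
10 slices × 20 phases, 256² matrix at 1.4 mm (358 mm field of view), 10 mm
slice spacing, EDV 150 mL, EF 0.60, blood/myocardium/background intensities
100/40/10 a.u., Gaussian noise σ = 5.  Noise is Gaussian rather than Rician:
at this SNR the Rician distribution is indistinguishable from Gaussian in
the blood and myocardium and only mildly skewed in the air background, which
no stage of the pipeline relies on.  An optional per-slice in-plane shift
emulates breath-hold misregistration.  Truth masks are the noise-free cavity
masks; truth volumes are disk summations over them.

What the phantom does *not* emulate — and hence what passing tests do not
show about clinical data: papillary muscles and trabeculation, through-plane
motion of the valve plane, intensity shading/bias fields, partial-volume
edges (boundaries are sharp before noise), arrhythmic or mis-gated frames,
and the anatomy of the right ventricle.  The basal distractor at full blood
intensity is the worst case for the growth engine (the leak is present from
the first threshold and is caught only by the continuity stage), but it is
geometrically simpler than a real aortic root.

## Numerical choices and degenerate inputs

* Angular resolution 1°, radial step 0.5 px, background-run length 2 px for
  polar maps; termination angles are therefore accurate to ~1°.
* A zero-area reference in the jump ratio, or an undefined centroid from an
  empty mask, compares as `+inf` — always a jump.
* An empty mid-ventricular cell aborts the run: nothing downstream is
  trustworthy if the anchor failed.
* Hough accumulator ties within a 10⁻³ relative tolerance are resolved by
  the documented radius/row/column order; an accumulator peak below 0.25
  (normalised) is treated as "no moving round object".
* Frames whose seeding or growth fails outright yield empty masks rather
  than aborting the sweep; the jump rules then exclude them.
* Cone extrapolation clamps at zero when the radius extrapolates past the
  apex; it never returns a negative area.
* The phantom refuses parameter combinations whose structures would not fit
  the field of view.

## Problem sizes in the test suite

The test suite exercises the full pipeline at the standard 10 × 20 × 256²
study size (a few seconds end to end) and uses 8 × 20 × 128² phantoms with
the field of view preserved for per-stage tests and the 50-phantom
localization sweep; these sizes keep the whole suite around a minute while
leaving every stage's geometry (cavity radii of 4–20 px) in the regime the
algorithm targets.

## Known limitations

* The growth engine is a reconstruction: the original method cites an
  earlier validated implementation whose exact stopping rule is not public.
  Every constant of the reconstruction is exposed and the leak/plateau rules
  are property-tested, but numerical parity with the original cannot be
  claimed.
* Basal interrogation examines only the first jump slice per phase; a stack
  with two junk slices below the true base would need the jump rules to flag
  both (they typically do, via the zero-area/`+inf` rule).
* Apical cells repaired by estimation carry areas but no masks; mask outputs
  are empty there by design, and volumetry uses the areas.
* `J_max`, `D_max` are fixed empirical defaults; no re-learning from data is
  attempted.
* ED/ES are curve extrema; bi-phasic pathological curves with a plateau
  could tie, resolved to the earliest phase.
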