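# archlen

Anterior dental-arch length from a cubic-parabola arch model: calculation,
treatment prediction, and method-agreement validation.

## The problem

When orthodontists resolve anterior crowding or spacing, they change the
inclination or position of the incisors — and with it the length of the
anterior dental arch (canine to canine through the incisal point). Predicting
how much space a planned incisor movement gains or loses is central to
personalised treatment planning: it informs decisions between proclination,
arch expansion, enamel reduction and extraction.

`archlen` implements a mathematical–geometrical model of the anterior arch
for this purpose, together with the machinery needed to validate it against
(emulated) cast measurements. It is aimed at orthodontic researchers and at
anyone building diagnostic tooling on top of 2-D cast analysis.

## The model

The anterior arch is a third-degree parabola in the occlusal plane. With the
x-axis through the distal canine contact points, the y-axis on the raphe
median plane, sagittal depth *L* (mm) and half arch width *W* = aaw/2 (mm):

```
f(x) = (L / W³)·x³ − L,    a = L / W³  (openness factor)
```

Arch length follows by line integration, doubled for the symmetric left half:

```
AL = 2 ∫₀^W √(1 + 9 L²/W⁶ · x⁴) dx
```

A planned incisor movement read from a lateral cephalogram — an inclination
change Δ∢ (degrees, tipping about the centre of rotation at distance *c* from
the incisal edge) plus a bodily sagittal translation — maps to a sagittal
incisal-point displacement Δs and a vertical displacement Δv by plane
trigonometry (e.g. upper jaw, θ = ∢1/NL − ∢OcP/NL):

```
Δs(tipping) = c·(cos(θ + Δ∢) − cos θ)        Δv = −c·(sin(θ + Δ∢) − sin θ)
Δs(total)   = Δs(tipping) + Δs(translation)
```

The post-treatment length AL_T1 is the same integral evaluated at
L + Δs(total) and (aaw + Δaaw)/2; ΔAL = AL_T1 − AL_T0.

Validation compares the polyline-measured arch length (the cast-measurement
procedure: 13 reference points, 12 linear subsections) with the calculated
one using Lin's concordance correlation coefficient, the intraclass
correlation coefficient, Bland–Altman limits of agreement and absolute
differences — on synthetic cohorts whose arch dimensions follow the
descriptive statistics of a treated orthodontic population.

## Worked example

A patient with upper-arch depth L = 13.9 mm and width aaw = 36.4 mm is
planned for +5° of upper-incisor inclination change (c = 22 mm,
∢1/NL = 110°, ∢OcP/NL = 10°) plus 3 mm of anterior bodily translation:

```
$ archlen predict --jaw upper --c 22 --incisor-angle 110 --ocp-angle 10 \
      --delta-inclination 5 --translation 3 --L 13.9 --aaw 36.4
delta_s_tipping_mm,-1.874
delta_s_total_mm,1.126
delta_v_mm,0.415
AL_T0_mm,49.652
AL_T1_mm,51.350
delta_AL_mm,1.698
```

The tipping term is −1.874 mm: with the tipping formula applied literally, a
*positive* inclination change moves the upper incisal point posteriorly at
typical angle configurations (the sign convention is documented in
`archlen.cephalometrics`). Translation dominates here, the incisal point
moves 1.126 mm forward, the bite opens by 0.415 mm at the upper incisor, and
the anterior arch gains 1.698 mm of length.

The same quantities are available as library calls:

```python
>>> from archlen import ArchGeometry, half_arch_length
>>> half_arch_length(ArchGeometry(L=13.9, W=18.2))   # one-sided AL, mm
24.826197337312713
```

Other subcommands: `archlen compute <table.csv>` (arch lengths for a cast
table), `archlen simulate --n 50 --seed 1 --out cohort.csv` (synthetic
cohort), `archlen validate cohort.csv --jaw upper --timepoint T0` (agreement
report, optionally with a Bland–Altman plot).

## Layout

- `archlen.arch_geometry` — the parabola model and its arc-length integrals
- `archlen.cephalometrics` — angle trigonometry, angle conversions, occlusal-plane sensitivity
- `archlen.measurement` — polyline measurement emulation and synthetic cohorts
- `archlen.agreement` — CCC, ICC, Bland–Altman, absolute-difference summaries
- `archlen.io`, `archlen.cli` — validated CSV parsing and the command line

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
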