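# stroketriage

Geospatial decision analysis of pre-hospital triage for acute ischemic
stroke (AIS).

Patients with AIS benefit from fast intravenous thrombolysis, and — when a
large vessel occlusion (LVO) is present — from fast mechanical
thrombectomy (MT). Thrombolysis is offered at primary stroke centers
(PSCs), MT only at comprehensive stroke centers (CSCs), so emergency
crews in the field face a transport decision with unknown vessel status.
Classically the choice is binary: nearest PSC ("drip-and-ship") vs
nearest CSC ("mothership"). This package quantifies how often that
binary framing is too narrow: a PSC that is *not* nearest to the scene,
but lies toward a CSC, can be a strictly better drip-and-ship station
than the nearest PSC.

It is aimed at health-services researchers and stroke-system planners
who want to simulate stroke-care geographies, map triage sub-regions,
and weigh the trade-offs of "higher-order" transport options.

## Model

Centers are placed in a disc-shaped incident region (radius `R` in
driving-time minutes) by a homogeneous spatial Poisson point process
conditioned on the counts (`n_CSC` CSCs, `n_PSC` PSCs i.i.d. uniform on
the disc); travel time between points is the Euclidean distance. For a
scene location the **admissible destinations** are the nearest CSC, the
nearest PSC, and every farther PSC that strictly shortens the total
time-to-CSC-via-PSC relative to all scene-closer PSCs — the Pareto
frontier of (time to PSC, time to CSC via that PSC). Locations are
labelled by their option count: *unconditional CSC catchment* (1),
*simple triage* (2), *higher-order triage* (≥ 3).

For each additionally considered PSC (admissible, beyond the nearest
one), two benefit/harm ratios are evaluated:

```
BHR_PSC = [(d_PSC1 + d_Transfer1) − (d_PSC2 + d_Transfer2)] / (d_PSC2 − d_PSC1)
BHR_CSC = (d_CSC − d_PSC2) / [(d_PSC2 + DIDO + d_Transfer2) − d_CSC]
```

`BHR_PSC` weighs the thrombectomy time gained against the thrombolysis
time lost relative to the nearest PSC; `BHR_CSC` weighs thrombolysis
gained against thrombectomy lost relative to direct CSC transport.
`DIDO` is the door-in-door-out time at the PSC (default 60 min).
A patient with LVO probability `p` is expected to benefit from a
higher-order option when its `BHR_PSC` exceeds
`(1 − p)/p × E_lysis/E_MT`, with per-minute outcome effects
`E_lysis = 1.8` and `E_MT = 4.2` disability-adjusted life-days/min by
default.

A `realworld` mode loads user-supplied center tables (`id,level,lat,lon`
CSV) with haversine-speed or matrix travel times in place of the
abstract disc.

## Worked example

The three-destination scene with driving times `d_PSC1 = 13`,
`d_Transfer1 = 55`, `d_PSC2 = 24`, `d_Transfer2 = 16`, `d_CSC = 43` min:

```python
>>> import stroketriage as st
>>> st.bhr_vs_nearest_psc(13, 55, 24, 16)   # 28/11
2.5454545454545454
>>> st.bhr_vs_nearest_csc(43, 24, 16, dido=60)  # 19/57
0.3333333333333333
```

Choosing the farther PSC gains 28 min of thrombectomy time per 11 min of
thrombolysis delay (BHR_PSC ≈ 2.55), so even a patient with only 30%
LVO probability (cutoff 1.0) is expected to benefit. The corresponding
command-line tools:

```sh
$ stroke-triage cutoff
p_lvo,cutoff
0.1,3.8571
0.3,1.0000
0.5,0.4286

$ stroke-triage map --n-csc 2 --n-psc 5 --radius 30 --seed 3 --out out/demo
lattice points: 31417
triage fraction: 0.535
higher-order fraction: 0.050
spatial median BHR_PSC: 1.01
```

i.e. in this particular random 2-CSC/5-PSC geography, a triage decision
is needed on 53.5% of the region's area and more than two destinations
must be weighed on 5.0% of it. `stroke-triage simulate` runs the full
replicated study (CSC 1–4 × PSC 2–10, 50 replicates each) and writes
per-combination medians/IQRs plus a range report; `--figures` adds maps
and boxplot panels.

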