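# neuroignite

Whole-brain dynamics analysis of parcellated resting-state fMRI for
neuro-oncology cohorts: **intrinsic ignition** and **metastability** from
event-based co-activation, per-region tumor involvement, and the group-,
region- and network-level statistics that compare brain-tumor patients
(diffuse glioma-like vs focal meningioma-like) with controls. A synthetic
cohort generator with known ground truth makes every stage testable without
any data download.

Intended for researchers analyzing parcellated BOLD time series (e.g.
Shen-268 regions, Yeo-7 networks) who want the full pipeline — signal
conditioning, event metrics, tumor-overlap mapping, nonparametric group
tests with multiplicity control, crossed-random-effects mixed models with
Satterthwaite tests, correlation-graph analysis and cognition coupling —
as a reusable, tested library.

## The metrics

For each region *i*, the band-passed (0.01–0.07 Hz), outlier-winsorized,
z-scored signal *z<sub>i</sub>(t)* is binarized into driving events
σ<sub>i</sub>(t) = 1 when *z<sub>i</sub>* crosses θ = 0 from below. For a
driving event of node *n* at time *t*, the instantaneous co-activation
graph **A**(τ) (nodes connected iff both have events at τ) is evaluated at
every step of the window *t* ≤ τ ≤ *t* + *T*<sub>win</sub>, and global
integration Φ(τ) is the size of its largest connected component. The
event's integration is max<sub>τ</sub> Φ(τ);

- **intrinsic ignition** of node *n* = mean of these maxima over its events,
- **metastability** of node *n* = their sample standard deviation.

*T*<sub>win</sub> preserves a fixed 16.8 s physical duration across mixed
repetition times: 7 TRs at TR = 2400 ms, 8 TRs at TR = 2100 ms, and
round(16800/TR) in general. Patient region metrics are expressed as
ΔIM = IM<sub>subject</sub> − mean(IM<sub>control</sub>) (negative =
reduction) and modelled as
`ΔIM ~ TumorPercentage + (TumorPercentage | SubID) + (1 | RegionID)`
by REML with Satterthwaite degrees of freedom.

## Worked example

`examples/` holds one short script per capability. For instance, the
sensitivity analysis (`python examples/03_sensitivity_analysis.py`) prints

```
meningioma vs control  (n=14 vs 10, Laplace-parent ARE 1.5):
  minimum detectable d = 0.97
  with metric SD 0.024: minimum detectable difference = 0.023
glioma vs control  (n=10 vs 10, Laplace-parent ARE 1.5):
  minimum detectable d = 1.06
  with metric SD 0.017: minimum detectable difference = 0.018
```

— the smallest standardized group difference (Cohen's d) a two-sided
Wilcoxon–Mann–Whitney test can detect at α = 0.05 and power 0.8 with those
group sizes, and its conversion to raw metric units. The network/cognition
script (`python examples/06_rsn_and_cognition.py`) prints

```
control: 21 of 21 metastability edges at r >= 0.4 (mean r 0.83)
glioma: 17 of 21 metastability edges at r >= 0.4 (mean r 0.57)

latency by group: Kruskal-Wallis H=0.36, df=2, p=0.83 (no gross behavioural deficit)
DMN ignition vs latency, control: r=-0.93, p=0.001
DMN ignition vs latency, glioma: r=-0.02, p=0.957
interaction (glioma slope minus control slope): +56.7 ms per ignition unit, p=0.001
```

— attenuated cohorts keep fewer strong metastability correlations, raw
response latencies do not differ by group, yet the negative
ignition–latency coupling present in controls is absent in patients, and
the interaction model quantifies that decoupling.

## Pipeline and CLI

`neuroignite.pipeline.run_pipeline(RunConfig(...))` executes the full
analysis (synthetic, pre-parcellated TSV, or NIfTI + atlas input) and
writes TSV/JSON artifacts plus a checksummed manifest; a thin CLI wraps it:

```bash
ignite synth --out cohort/ --seed 7          # write a synthetic cohort
ignite validate --config config.yaml         # pre-flight input checks
ignite run --config config.yaml              # full analysis
```

Runs are deterministic given config + seed (byte-identical artifacts).

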