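# Methods

## Model

`capouch` simulates cytosolic Ca²⁺ signaling in a planar epithelial sheet
(the *Drosophila* wing-disc pouch is the motivating system).  Each cell
carries three state variables:

- `p` — cytosolic IP₃ concentration (μM),
- `c` — cytosolic Ca²⁺ concentration (μM),
- `r` — fraction of IP₃ receptors (IP₃R) not inactivated by Ca²⁺.

The ER Ca²⁺ concentration `s` is slaved algebraically to `c` through
`c + β·s = c_tot`, so the cytosol/ER conservation law holds exactly at
every sample by construction rather than up to solver error.

Per cell *i* with stimulation strength `V_PLC,i`:

```
dp_i/dt = Jp_i + V_PLC,i · c_i²/(K_PLC² + c_i²) − k_5P · p_i
dc_i/dt = Jc_i + [k₁·(r_i · c_i/(K_a+c_i) · p_i/(K_p+p_i))³ + k₂]·(s_i − c_i)
          − V_SERCA · c_i²/(c_i² + K_SERCA²)
dr_i/dt = (k_τ⁴ + c_i⁴)/(τ_max · k_τ⁴) · (1 − r_i·(K_r + c_i)/K_r)
```

The `r` equation above is the default (`receptor_variant="modified"`):
Ca²⁺ accelerates receptor inactivation/recovery through the quartic
factor.  A constant-time-constant variant
`dr/dt = (1/τ_r)·(1 − r(K_r+c)/K_r)` is retained for comparison
(`receptor_variant="constant_tau"`).  At the resting branch the Ca²⁺
level is so low (c* ≈ 0.073 μM) that the quartic factor is 1 + 5.6·10⁻⁶;
both variants therefore place the single-cell oscillation onset at the
same V_PLC (see below), and the choice only matters for the shape and
timing of the large excursions.

Plasma-membrane Ca²⁺ fluxes, stochastic channel gating and explicit
DAG/PIP₂ dynamics are outside the model.

### Units and τ_max

All concentrations are μM, all times seconds, all lengths dimensionless
(cell diameters).  `τ_max = 800` is interpreted as a time constant in
seconds: as the prefactor of the receptor relaxation it must carry units
of time for the equation to be dimensionally consistent.

### Gap-junction coupling

Cells exchange IP₃ and Ca²⁺ with their geometric neighbours in
discrete-Laplacian form

```
Jx_i = F · Σ_{j∈N_i} l_ij · (x_j − x_i),     x ∈ {p, c},  F ∈ {F_p, F_c}
```

where `l_ij` is the shared boundary length.  This form is zero at uniform
concentration and conserves the tissue totals of `p` and `c` exactly
(antisymmetry), which the tests verify on pure-diffusion runs.  The
tissue boundary is no-flux: cells exchange only across listed edges.

Permeabilities are per unit shared-boundary length.  Because coordinates
are normalised so the mean cell diameter is 1, `l_ij` is dimensionless
and the baseline `F_p = 0.005`, `F_c = 0.0005` are used as printed.

## Tissue geometry

The synthetic pouch emulates a segmented columnar epithelium: points are
sampled uniformly in an ellipse of aspect ratio 1.3, tessellated
(Voronoi, clipped to the ellipse via a ring of far ghost generators), and
relaxed by 4 rounds of Lloyd's algorithm (each generator moves to its
clipped-cell centroid).  This produces near-hexagonal packing: interior
cells average ≈ 6.0 neighbours, matching the topology of a relaxed
epithelium.  Shared boundary lengths are measured as the geometric
intersection of adjacent cell boundaries (snapped to a 10⁻⁹ grid so
abutting polygons coincide exactly).  A cell is flagged as a boundary
cell when its perimeter exceeds the sum of its shared edges.

What the generator does *not* emulate: cell divisions and
rearrangements, area gradients across the pouch, the peripodial layer,
and the exact size distribution of a segmented disc.  Tests passing on
these tissues show that the signaling conclusions follow from
near-hexagonal local topology and boundary-length-weighted coupling, not
from any particular real geometry.

## Stimulation fields

`V_PLC` is the per-cell maximal IP₃ production rate, the lumped
stimulation-strength parameter.  A scenario field draws a small set of
**initiator cells** (default 2 % of the tissue, at least one) uniformly
without replacement, gives them V_PLC above the oscillation threshold,
and draws all remaining **standby cells** from a class-specific uniform
range:

| class      | standby V_PLC | initiator V_PLC |
|------------|---------------|-----------------|
| spikes     | 0.1–0.5       | 1.4–1.5         |
| ICT        | 0.25–0.60     | 1.4–1.5         |
| ICW        | 0.4–0.8       | 1.4–1.5         |
| fluttering | 1.4–1.5       | 1.4–1.5         |

Developmental scaling runs fix standby V_PLC at 0.40 with initiators on
1.3–1.5 and vary either the initiator count
(`N_init = round(8000·N⁻⁰·⁸)`, clamped to [1, N]) or the permeability
(`F_p = 800·N⁻¹·⁸`, `F_c = 0.1·F_p`, 65 initiators).  Sensitivity sweeps
reuse one frozen wave-producing field (standby 0.7–1.0) across all sweep
points so that metric differences reflect the swept parameter only.

## Integration and initial conditions

The stacked 3N system is integrated with BDF using the analytic sparse
Jacobian (per-cell reaction blocks plus the coupling Laplacian), at
rtol 10⁻⁶ / atol 10⁻⁹ by default, sampled every 10 s over 1 h — the
cadence and duration of the live-imaging experiments the simulations
emulate.  Halving the tolerances changes sampled subthreshold
trajectories by < 10⁻⁴ relative; with coupling removed the tissue
reproduces independent single-cell integrations to < 10⁻⁶ pointwise at
rtol 10⁻¹¹.

All runs start from the uniform resting state — the fixed point of an
isolated cell at V_PLC = 0 (p = 0, c ≈ 0.0586 μM, r = K_r/(K_r+c)) —
with spatial heterogeneity entering only through the V_PLC field.  Two
observation conventions follow from the experiments being emulated:

- **Acute stimulation** (the four pattern scenarios, scaling runs,
  sweeps): agonist arrives at t = 0, so the evoked response from rest is
  the signal and the full hour is reported.
- **Basal equilibrium** (the gap-junction block scenario): the tissue
  sits unstimulated in basal media, so a 1200 s equilibration burn-in is
  integrated and discarded before the reported hour.  Without it, the
  one-off relaxation transient of the uniform start would be scored as
  Ca²⁺ activity even in conditions where the equilibrated tissue is
  silent.

## Bifurcation analysis

Fixed points are found by eliminating `p*` and `r*` analytically and
bracketing the scalar Ca²⁺ balance on a dense grid over (0, c_tot); when
the branch folds (around V_PLC ≈ 0.78 at baseline) the lowest-Ca²⁺
(resting) root is returned.  Stability comes from the analytic 3×3
Jacobian (verified against central finite differences).  The oscillation
onset HB₁ is located by bisection on the real part of the
complex-conjugate eigenvalue pair; a real eigenvalue crossing
(saddle-node) is not reported as a Hopf.  Two numerical facts matter:

- The complex pair exists only on a narrow V_PLC window (~0.007 wide at
  baseline) around the crossing; the scan grid (step 0.002 by default)
  must land inside it.
- The onset is subcritical: the stable cycle is born at large amplitude
  (c_max − c_min > 1 μM just above threshold) with long periods
  (≈ 1900 s at V_PLC = 0.8, shortening to ≈ 500 s at 1.45).  Cycle
  extrema are therefore read from a 7200 s integration discarding a
  1200 s transient.  Unstable cycles are not tracked.

At Table-1 baseline the threshold is V_PLC* = 0.7738, for both receptor
variants (the steady state is variant-independent and the variant factor
is ≈ 1 at resting Ca²⁺).  A gap-junction leak into resting neighbours
(clamped reservoir, total shared boundary L = 6 by default) raises the
threshold monotonically in F_p.  The threshold is nearly insensitive to
k_τ and τ_max (shifts < 10⁻³ for twofold changes) — these parameters
shape the oscillation, not its onset.

## Quantification

- **F/F₀ normalisation**: each cell's trace is divided by its 10th
  percentile.  A low percentile is robust to long active episodes; the
  result is invariant to uniform rescaling of the raw trace.
- **Spike detection**: maximal excursions of F/F₀ above 1.5; excursions
  separated by < 20 s merge.  Width at half maximum is measured at
  `1 + (peak−1)/2` — halfway between baseline and peak — with linear
  interpolation of crossing times, which makes the triangular-pulse case
  exact.
- **Frequency**: reciprocal mean peak-to-peak interval; undefined (None,
  never zero) with fewer than two peaks.
- **Kymographs**: cells intersecting a line, ordered by centroid
  projection, intensity per sample.

### Pattern classifier

The classifier replaces by-eye scoring with a fixed rubric.  Per frame a
cell is active when F/F₀ > 1.5.  Active (cell, frame) pairs are grouped
into events by connected components over: same cell in consecutive
frames, adjacent cells in the same frame, and adjacent cells in
consecutive frames (so a front advancing ~1 cell per 10 s frame remains
one event).  Precedence and rules:

1. **fluttering** — ≥ 50 % of cells active in ≥ 20 % of frames.  The
   time fraction is set below the duty cycle of a tissue-wide
   synchronized oscillation (measured 0.29–0.35 of frames at baseline
   fluttering conditions) and an order of magnitude above what dense
   wave activity produces (≤ 0.03); demanding 50 % of frames would
   conflate duty cycle with globality and separate nothing.
2. **none** — no events.
3. **ICW** — some event spans ≥ 5 % of the tissue (at least 4 cells)
   *and* its per-frame active-centroid travels > 2 cell diameters.
   Propagation is the primary wave discriminator; the span gate is kept
   low because a wave's recruitment depth (~10–30 cells) is set by the
   kinetics, not by the cell count, and a large fixed tissue fraction
   would over-demand on small simulated tissues.
4. **ICT** — some event spans > 3 cells, none qualifies as a wave.
5. **spikes** — all events span ≤ 3 cells.

All thresholds live in `ClassifierConfig` and are frozen at these
defaults for the acceptance checks.

Known limitation: when a large fraction of cells oscillate autonomously
(e.g. standby V_PLC 0.7–1.0 with coupling reduced to a few percent of
baseline), dense asynchronous spiking can percolate through cell
adjacency into one giant spatiotemporal component that the rubric reads
as tissue-scale activity, where a human scorer would report spikes or
transients.  The rubric is reliable for the sparse-initiator scenarios
it is frozen for.

- **Integrated activity**: `Σ_cells Σ_samples max(F/F₀ − 1, 0)·Δt`;
  spikes-per-area divides the tissue spike count by the pouch area (in
  squared cell diameters).

## Problem sizes

Scenario-level analyses use 200-cell tissues (five seeds for the
pattern-class checks), the decoupling check 50 cells, and the
developmental-scaling runs 100–800 cells — sizes at which all of the
studied transitions are already expressed while a full scenario
integrates in seconds.  All randomness (geometry sampling, initiator
placement, V_PLC draws) flows from explicit integer seeds through
independent child generators, so every result in the README and in
`scripts/acceptance.py` is exactly reproducible.

## Known limitations

- Unstable limit cycles and two-parameter continuation are not
  computed; the bifurcation module reports steady states, stability,
  and stable-cycle extrema only.
- The class boundary between single-cell spikes and small transients is
  sharp (3 cells) and can flip near-boundary runs between the two
  labels on some seeds; the ICT scenario in particular straddles it.
- Tissues are static: no growth, division, rearrangement or mechanics.
- The classifier limitation for dense autonomous spiking described
  above.
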