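# Methods

## Model

The simulator is a stochastic cellular automaton on an `L×L×L` lattice whose
agent — a 1 mm³ "tumour voxel" — coarse-grains roughly 10⁶ cells. It makes
the usual simplifying assumptions of this model class: no tumour
microenvironment or immune interaction, fixed (environment-independent)
driver advantages, proliferation-coupled mutation (drivers arise only at
division, so DNA replication and chromosome mis-segregation are the implied
sources), and no treatment. A second mutation of the same gene never occurs
within one voxel, but distinct voxels can acquire independent alleles of the
same gene — parallel evolution, which the analysis layer tracks by unique
allele ids.

Each step executes death → depth-field refresh → growth → driver
acquisition → necrosis. The per-step phase order and the following
intra-step conventions are deliberate choices where the model class leaves
them open:

- within the growth phase, dividing parents are visited in a fresh uniform
  random permutation, and surface-eligibility/emptiness is re-checked at
  placement time; sites freed by this step's deaths are immediately
  reusable. Randomised sequential update avoids directional artefacts.
- only the newly placed voxel of a division is the "daughter" tested for
  driver acquisition (the in-place voxel is the continuing parent).
- Volume-Growth pushing samples 10 of the 26 lattice orientations, ranks
  the candidate sites by the shared depth field regardless of occupancy
  (ties broken uniformly), and shifts the occupied run one step outward
  along the chosen orientation; the displaced voxels keep their order.
- contact with the lattice boundary raises an error rather than clipping;
  choose `L` with generous margin (fit subclone "buds" can overshoot the
  mean radius by > 50 %).

### The depth field ("distance from the tumour surface")

Necrosis and Volume-Growth placement both need a voxel's distance from the
tumour surface. The surface is the **exterior**: the empty region
face-connected to the lattice border. Internal cavities — holes opened by
the 5 %-per-step random death, or by necrosis itself — are filled
(`binary_fill_holes`) before the exact Euclidean distance transform.
Without this, the scattered interior holes of any death-enabled run keep
every voxel within 1–2 mm of *some* empty site and necrosis at
`d_necrosis = 15 mm` would never fire at all. Empty sites keep depth 0, so
volume-mode placement still prefers an adjacent free site (a zero-length
push). The brute-force oracle in the tests mirrors this exterior
definition; on cavity-free geometries it coincides with the naive
nearest-empty-site distance.

### Determinism and replay

Step `t` draws from a dedicated generator seeded by
`SeedSequence(seed, spawn_key=(t,))` (PCG64). Consequences: identical
config + seed reproduce a byte-identical snapshot series, and a snapshot
resumed under the same master seed continues exactly as the uninterrupted
run — which is how the replay resume-consistency test works without
serialising raw generator state. Replay replicates simply restore the
snapshot and continue under their own seeds.

Runs in which the founder lineage dies out (probability ≈ p_death/p_growth
≈ 0.2 at baseline) never reach the stopping size; ensemble helpers
(`run_surviving`) condition on non-extinction by retrying under a seed
derived deterministically from (seed, attempt). Study ensembles therefore
describe tumours that actually grew, matching how simulated cohorts are
defined by reaching the stopping size.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p_growth_initial` | 0.25 /step | baseline division probability |
| `p_death` | 0.05 /step | random death probability |
| `p_driver` | 6×10⁻⁴ | per-event gene-mutation acquisition probability per daughter (2×10⁻⁴–1×10⁻³ is the studied range) |
| SCNA factor | 0.001 | SCNAs acquire at `0.001·p_driver`; PBRM1/BAP1 mutations restore `p_driver` |
| `s` | 1.0 | selective coefficient of the saturated model |
| `p_necrosis`, `d_necrosis` | 0.5, 15 mm | necrotic death beyond 15 mm depth |
| `L`, `stop_size` | 200, 10⁶ | lattice side and stopping size (full scale) |

One simulation step is the time unit throughout; no calendar-time
calibration is attempted. The 26-event driver panel ships the explicitly
canonical structure — VHL/3p loss truncal, PBRM1/BAP1 as SCNA-rate
enhancers, 7q+/20q+/4q−/8p− as the strongest (maximal-tier) drivers, 12
gene mutations vs 14 SCNAs — while the remaining membership and the
Ki67-association rank order are a documented, file-configurable default
(`load_panel`): the exact ranking is not public at printed precision.
Truncal events carry no growth advantage in either selection model, so the
founder always divides at `p_init`; in the saturated model a voxel's
probability is set by the highest tier it harbours (the only combination
rule consistent with saturation at two advantage levels); additive
increments use `s_k(r) = min_sk + (r−1)·Δs_k` with three named presets
(weak / intermediate / strong).

## Subclone accounting

Two conventions coexist, used for different quantities:

- **CCF, Shannon, detectable counts** use the *most-derived partition*:
  every voxel belongs to exactly one clone (its latest label), CCFs sum to
  1, and the parental clone counts as a clone. Detectability is strict
  CCF > 0.01; clone counting against a coarser floor (CCF ≥ 0.05,
  inclusive) is available.
- **Microdiversity** uses *nested membership*: a voxel witnesses its
  subclone and every ancestor, and the parental clone is not a subclone.
  This mirrors how multi-region sequencing counts subclones in a region
  (nested VAF clusters) and is what makes deep-lineage regions hotspots.
  The alternative distinct-label count is available
  (`microdiversity_map(..., counting="labels")`). Under label counting the
  Surface-vs-Volume ordering of hotspot exponents is lost at reduced
  scale; under nested counting it is decisive (k ≈ 3.6 vs ≈ 2.4 in the
  reduced ensemble).

## Spatial analyses

Slices are the plane `z = z0` (lattice centre by default). The tumour
centre is the **centroid of occupied slice sites**, not the lattice centre
(robust to drift; both definitions of the hotspot `d1` reference are
available by passing a slice built around either). The contour is traced by
Moore boundary following (8-connectivity) on the largest connected
component; contour smoothing is a cyclic moving average (default window 5
points), calibrated so a digital disc's smoothed perimeter is within a few
per cent of `2πr`. Circularity is the isoperimetric ratio
`4π·Area/Perimeter²` — the dimensionally consistent form of the printed
`4π·Area/Perimeter`, and the only reading under which a circle scores 1 at
any size.

Hotspot distances use the raw (lattice) contour points, so a window centred
on the contour has exactly `d = 1`. The sliding window has stride 1 mm and
windows with no occupied site are excluded. Biopsy grids anchor at
`spacing/2` from the lattice origin (100 candidate centres on the 200 mm
lattice at the default 20 mm spacing / 5 mm radius). Youngest-subclone
positions are the registry-recorded initiating voxel positions, kept
current under Volume-Growth pushes (frozen at the last position if the
voxel later dies).

The power-law exponent is fitted by nonlinear least squares of the
empirical CDF against `d^k` (coefficient fixed at 1 on the unit support;
`curve_fit`), with a log–log linear fit as a cross-check option, and a
bootstrap of 100 resamples of 400 points. Degenerate inputs (all-identical
distances) are flagged rather than fitted. A single 400-point draw carries
sampling noise of ≈ 0.15 in the fitted exponent, so tests and the
acceptance script assert/report the mean of the bootstrap medians over
independent replicate draws of the same protocol — an estimate of the same
quantity with noise ≈ 0.05 — rather than gambling a point assertion on one
draw.

## Temporal analyses

Slice "diameter" is the equivalent circular diameter `2√(A/π)` (stable for
lobed shapes). KDE over (diameter, subclone count) uses a Gaussian kernel
with Scott's rule by default; the 90 % probability contour is the density
superlevel set holding 90 % of mass; singular covariances (collinear or
constant axes) receive a minuscule deterministic jitter, all-identical
point sets are rejected. Flow fields bin per-snapshot displacements in the
(subclone count, mean drivers) plane on uniform rectangular bins, masking
bins with fewer than 3 observations. Replay divergence keys clone
frequencies by driver-event set (allele ids ignored, so parallel hits of
the same genes compare as the same outcome) and reports pairwise
Jensen–Shannon divergence in nats (maximum ln 2); keying by allele identity
is a documented alternative via the registry's allele sets. Time-course
snapshots whose analysis plane is momentarily empty (tiny early tumours)
are skipped.

## Cohort interface

Region tables carry per-region coordinates, clone/subclone counts,
semicolon-separated event labels and group labels. Margins are explicit
polygons when supplied, else the convex hull of the tumour's regions — a
documented limitation, since real specimen margins are not convex. `d1` is
measured to the margin-polygon area centroid, `d2` to the nearest point of
the polygon boundary. The hotspot proxy defaults to regions with ≥ 1
subclone (the stricter ≥ 2 reading is a parameter). Group comparisons fit
each group's hotspot-proxy distances with the same bootstrap power law and
compare exponent samples by the two-sided Wilcoxon rank-sum test.

## Synthetic data

The uniform-disc generator *is* the null model: points uniform in a disc of
radius R give `d = r/R` with CDF `d²`, so a correct pipeline fits k = 2.
The synthetic region-table generator emulates a multi-region cohort:
margins are regular 72-gons (a circle at the fidelity real margins would
support), hotspot-proxy regions sit at planted normalised distances
(`d = u^(1/k)` by inverse-CDF), filler regions are monoclonal, and parallel
events are planted with configured spans and margin depths. What it does
**not** emulate: sequencing noise, purity, irregular margins, spatially
correlated subclone counts within a tumour — so passing cohort tests shows
the pipeline recovers planted spatial laws, not that it is robust to every
artefact of real multi-region data.

## Reduced (desk-scale) study sizes

The full-scale condition (200³, 10⁶ voxels, 50–250 replicates) is available
through the same configs but the shipped tests run reduced ensembles,
chosen as the smallest sizes at which each phenomenon is expressed:

- growth-law fits and the Surface-vs-Volume diversification ordering:
  L = 60, stop 2×10⁴, 10–20 seeds per mode, saturated s = 1,
  `p_driver = 6×10⁻⁴`. Since a single reduced z0 slice rarely holds a
  hotspot, hotspot distances are pooled over every z-plane of each run
  (planes are statistically equivalent observation slices) and across
  replicate runs, as hotspots are pooled across repeat simulations at full
  scale.
- necrosis effect on central fitness: L = 96, stop 10⁵ (equivalent radius
  ≈ 29 mm), so the necrotic core (> 15 mm deep) is active for most of the
  run; 10 paired seeds with/without necrosis.
- replay repeatability trend: L = 48, stop 6×10³, replaying 3 replicates
  from an early (≥ 500 voxels) and a late (≥ 3000) snapshot of 10 base
  runs.

Expectations at these sizes: volume-mode populations grow by
`(1−p_death)(1+p_growth) ≈ 1.19` per step (the death-then-growth phase
order makes this the exact branching factor); surface-mode cube-root size
is linear in time; the reduced ensemble gives hotspot exponents ≈ 3.6
(surface) vs ≈ 2.4 (volume) and mean detectable-subclone counts ≈ 2.8 vs
≈ 2.2.

## Known limitations

- The late-time **collapse of clonal diversity** under necrosis is a
  full-scale, late-stage phenomenon: at the reduced sizes above, diversity
  is still rising when runs stop (collapse observed in only 2/10 reduced
  necrosis runs), so no test asserts it. The time-course machinery that
  would measure it at full scale is in `temporal_analysis`.
- Surface-mode hotspot edge-enrichment is much weaker under distinct-label
  counting than under the default nested counting; the counting convention
  is therefore load-bearing and exposed as a parameter.
- The driver panel's rank order and tier membership beyond the canonical
  named events are defaults, not measurements.
- Margin polygons for cohort data default to convex hulls; concave tumour
  outlines will understate `d2` for regions near concavities.
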