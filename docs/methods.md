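# Methods

`nucleakin` implements a kinetic analysis chain for heterogeneous ice
nucleation on a crystalline substrate: per-molecule ice polymorph
detection, collective-variable (CV) construction and selection, Markov
state model (MSM) estimation and validation, metastable lumping (PCCA+),
and transition path theory (TPT). This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
ground-truth generators do and do not emulate.

## Ice detection

Local structure is measured by neighbour-averaged Steinhardt bond-order
parameters. For molecule *i* with the set `N_i` of nearest oxygen
neighbours,

    q_{l,m}(j) = (1/N_j) * sum_{k in nbrs(j)} Y_{l,m}(r_j - r_k)
    qbar_l(i)  = sqrt( 4*pi/(2l+1) * sum_m | (1/(N_i+1)) *
                 sum_{j in {i} u nbrs(i)} q_{l,m}(j) |^2 )

with `Y_{l,m}` spherical harmonics on the unit minimum-image bond vector.
Averaging the complex `q_{l,m}` over the first shell before forming the
rotational invariant strongly sharpens the crystal/liquid separation.
Because only even `l` (4 and 6) are used, the sign convention of the bond
vector is immaterial.

Classification rules and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_neighbors_bulk` | 4 | tetrahedral coordination in the bulk |
| `n_neighbors_interface` | 3 | one bond is donated to the substrate |
| `qbar6_bulk` | 0.45 | bulk hexagonal-ice threshold |
| `qbar6_interface` | 0.5 | interface hexagonal threshold |
| `qbar4_low` / `qbar4_high` | 0.6 | interface hexagonal/rhombic split |
| `interface_z_cutoff` | 0.35 nm | interface band above the surface top (one hydrogen-bond length above the contact layer) |
| `cluster_cutoff` | 0.35 nm | O-O graph edge for nucleus clustering (first minimum of the O-O pair correlation of simulated water) |
| `layer_spacing` | 0.368 nm | c/2 of the hexagonal ice cell (c = 0.7357 nm) |

A molecule within `interface_z_cutoff` of the surface top uses the
interface rules; the rhombic condition (`qbar4 > 0.6`) is stated
unconditionally and therefore takes precedence when the hexagonal
condition also fires. Bulk molecules are never labelled rhombic: the
planar four-coordinated motif is surface-stabilized and its detection
presupposes the 3-neighbour rule. A frame without a recorded surface
(`surface_top_z = None`) is treated as homogeneous bulk; callers that
require a surface can pass `require_surface=True` to turn the missing
metadata into an error.

On ideal noiseless structures the detector gives `qbar6 = 0.567` for the
hexagonal-ice oxygen lattice (well above 0.45) and `qbar4 = 0.83`–`0.85`
for the square rhombic net with 3 neighbours (well above 0.6); uniformly
random liquid configurations cross the hexagonal threshold in under 1% of
molecules. These margins are what make the 0.01 nm default lattice noise
of the generators inconsequential.

Nucleus identification is single-linkage clustering on the ice-labelled
molecules with minimum-image O-O edges up to `cluster_cutoff`; ties
between equally large components go to the one containing the smallest
molecule index. Layers are `floor((z - surface_top_z)/layer_spacing)`,
clamped at 0, warning when a molecule sits more than 0.05 nm below the
surface top.

## Collective variables

The candidate pool holds 18 descriptors: layer-resolved hexagonal and
rhombic counts inside the largest nucleus, whole-frame totals, nucleus
geometry (lateral extent, height, gyration-eigenvalue sphericity) and the
highest occupied layer. The five CVs that carry the slow kinetics are the
total ice and rhombic ice in the largest nucleus and the nucleus
hexagonal ice in the 2nd, 3rd and upper layers ("layer1" in CV names is
the contact layer, internal index 0). Sphericity is defined here as the
smallest-to-largest eigenvalue ratio of the nucleus gyration tensor
(1 = sphere, 0 = planar); the count CVs need only labels, the geometric
ones also need coordinates and are reported as 0 when none are supplied.

## CV selection

Given mean-free instantaneous and time-lagged covariances `(C0, Ctau)`
(symmetric estimator over all `(t, t+tau)` pairs, lagged pairs never
crossing trajectory boundaries, `Ctau` symmetrized), subsets of columns
are scored by how well the restricted generalized eigenvalue problem
`Ctau v = lambda C0 v` reproduces the top-m eigenvalues of the full pool;
the Nystrom reconstruction `C[:,S] pinv(C[S,S]) C[S,:]` quantifies the
matrix-level error. Selection is greedy, one column at a time, minimizing
the squared top-m eigenvalue error, ties to the lower column index.
Numerical guards: `C0` is regularized by `1e-10 * trace/K` on the
diagonal; the sub-block pseudo-inverse truncates at relative tolerance
1e-10; eigenvalues are clipped into (0, 1) before `t = -tau/ln(lambda)`
(non-positive eigenvalues yield timescale 0 with a warning).

Timescales estimated from noisy observables at short lags are biased low
(observation noise inflates `C0`); the tests therefore evaluate timescale
recovery at a lag of 10 steps, where the bias for the emission noise used
(0.1 of a count separation) is within a few percent.

## Markov state models

CVs are standardized (zero mean, unit variance, global over trajectories)
before greedy k-centers clustering: the counts in the CV vector live on
comparable but differently scaled axes and the clustering metric should
be isotropic. The first center is a seeded uniform draw; every further
center is the frame farthest from the current centers, which covers the
data within twice the optimal covering radius. All randomness is explicit
(`seed` arguments); there is no global random state anywhere in the
package.

Transition counts use the sliding window at lag `tau` within each
trajectory. Estimation first trims to the largest strongly connected
component of the count graph. The non-reversible estimate row-normalizes
counts; the reversible maximum-likelihood estimate under detailed balance
iterates the standard self-consistent update

    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)

until the stationary law moves by less than 1e-10 (iteration cap 10^6;
failure raises, never silently falls back). Validation: implied
timescales `-tau/ln(lambda_i)` across lags (undefined, reported NaN, for
non-positive eigenvalues); a Chapman-Kolmogorov test comparing `T^k`
residence probabilities with re-estimation at lag `k*tau`, with bootstrap
bands over trajectories (or blocks of a single trajectory); and GMRQ
cross-validation with folds split by trajectory, scoring train-set
eigenvectors on test-set correlation matrices.

The study-scale defaults (1000 microstates, 8 macro-states) are exposed
as configuration; tests and examples run 40–100 microstates, which the
8-basin synthetic networks resolve comfortably.

## PCCA+

Macro-states come from the simplex structure of the top right
eigenvectors of a reversible transition matrix (computed through the
pi-symmetrized form, so the spectrum is real). The inner-simplex
algorithm picks the most spread-out eigenvector rows as vertices
(Gram-Schmidt on row differences), maps rows to memberships by the
inverse vertex transform, clips negative entries and renormalizes rows —
a deterministic feasibility projection, chosen over unconstrained
rotation refinement for reproducibility. Crisp assignments take the
argmax (ties to the lower macro index), and macro-states are relabelled
by their lowest microstate member for determinism. Non-reversible input
is rejected. Coarse-graining aggregates stationary flux:
`macro_T_AB = sum_{i in A, j in B} pi_i T_ij / pi_A`. All downstream
kinetics use crisp assignments.

## Transition path theory

Forward committors solve the discrete boundary-value problem by a sparse
direct solve (exact at these sizes, no iteration); backward committors
solve the time-reversed chain, and `q- = 1 - q+` holds for reversible
matrices. Reactive flux `f_ij = pi_i q-(i) T_ij q+(j)`, net flux
`max(0, f_ij - f_ji)`; the net flux is divergence-free at intermediate
states to machine precision. Pathways are extracted by iterative
max-bottleneck (widest-path) removal — the standard TPT decomposition —
which conserves the total flux exactly when run to completion.
Transition states are the microstates with committor inside a window,
default [0.45, 0.55]; for coarse models whose committors jump across 0.5
a wider window is the appropriate choice. MFPTs solve
`(I - T_restricted) m = lag_time` on non-target states. The nucleation
rate is `J = 1/(MFPT * V)` with `V` the simulated water volume; a
surface-area normalization is a trivial caller-side variant.

Chain synthesis (`sample_chain`) draws categorical steps from cumulative
rows, reproducibly under a fixed seed; it supports the ten-trajectory
millisecond-scale protocol used for MFPT estimation at study scale.

## Synthetic ground truth

`build_two_pathway_network` produces an 8-state row-stochastic matrix
with the topology of surface nucleation: liquid basin I, pre-nucleation
basin II, a direct classical branch II->IV, a mixed rhombic/hexagonal
intermediate III on the non-classical branch II->III->{IV,V}, and growth
states VI->{VII,VIII}. Self-probabilities equal the `metastability`
parameter (default 0.95, slowest relaxation ~70 steps; 0.99 gives >300).
The branch probability at II is tuned by bisection until TPT on the exact
matrix yields the requested classical flux fraction within 0.01.
Emissions are per-state Gaussian CV observations (default SD 5 counts
against inter-state separations of tens to hundreds), rounded and clipped
to non-negative integers; the hidden state sequence is returned for
recovery scoring, and `match_macrostates` aligns recovered macro-states
with generative basins by optimal assignment on mean CV signatures.

`build_lattice` provides the detector's ground truth: the wurtzite-type
hexagonal-ice oxygen lattice (a = 0.4519 nm, c = 0.7357 nm, O-O bond
0.276 nm) as a fully periodic crystal or as a finite slab cut between
bilayers so that both surface levels keep 3 of 4 neighbours (the physical
contact-layer geometry); a planar square rhombic monolayer at 0.276 nm
spacing placed inside the interface band; and a hard-sphere-rejection
liquid at 33 molecules/nm^3 with a 0.2 nm core. Gaussian displacement
noise (default 0.01 nm, far below the classification margins) is seeded.

What the generators do *not* emulate: real hydrogen-bond topology and
proton disorder (all detectors are oxygen-geometric), realistic water
dynamics within a basin (emissions are i.i.d. given the hidden state,
so microstate-level memory effects of real MD are absent), surface
lattice mismatch strain, and the liquid layer that covers a growing
nucleus in the simulated system — a vacuum-terminated slab therefore
frays at its top layer under the bulk rule, which is an artefact of the
vacuum, not of the detector. Passing recovery tests consequently show
correctness of the estimators under their own model assumptions, not
fidelity of any force field.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in a couple of minutes: detector fixtures with 64–288
molecules; oracle equivalence on 50-molecule frames at 1e-12; MSM
recovery and the end-to-end two-pathway study from 10^6 sampled steps
(4 x 250k and 10 x 100k), where the classical flux fraction is recovered
within 2 percentage points against a 5-point criterion and the slowest
timescale within a few percent against 15; committor/flux identities at
1e-10–1e-12; sampling cross-checks (MFPT, committor) at three standard
errors with fixed seeds. The millisecond, 4940-molecule scale of a real
study is reached by raising the same configuration knobs.

## Known limitations

- Orthorhombic boxes only; triclinic cells are rejected at parse time.
- Committor and MFPT solves are dense/direct; comfortable to a few
  thousand microstates, not designed for 10^5-state models.
- The nucleus unwrap assumes the cluster spans less than half the box in
  periodic directions; a percolating ice layer has no unambiguous unwrap.
- PCCA+ uses the deterministic inner-simplex construction without the
  optional rotation optimization; for strongly non-metastable matrices
  memberships can be coarse (they remain valid simplex vectors).
- The 18-member CV pool is a documented reconstruction: the five slow
  CVs are fixed by the physics, the remaining pool members are plausible
  geometric descriptors and are configurable.
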