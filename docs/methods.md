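# Methods

`unbindkit` implements a desk-scale version of a combined methodology for
ligand-unbinding kinetics: automated discovery of the collective
variables (CVs) that carry an unbinding event, free-energy reconstruction
along the resulting path, and a machine-learning analysis that ranks
which observables decide a trajectory's fate at the transition state
(TS).  Everything runs on stochastic model dynamics rather than all-atom
molecular dynamics; this note records the models, the tunable constants,
and the design choices made where the design was genuinely open.

## Dynamics engine

All sampling uses overdamped (high-friction) Langevin dynamics
integrated with first-order Euler-Maruyama,

    x_{t+1} = x_t - (dt/γ) ∇(V + bias)(x_t) + sqrt(2 kT dt / γ) ξ_t ,

with ξ_t standard normal.  Euler-Maruyama is the simplest scheme
consistent with overdamped dynamics; its known O(k·dt) bias on
stationary distributions is why free-energy tests use small steps
(`dt = 0.002–0.005` at stiffness ≲ 40).  Coordinates are in toy "Å",
energies in kT unless stated.  Friction may be set per coordinate: a
slow reaction coordinate coupled to a fast noise bath is modelled by
giving the slow mode a larger γ.  Frames may be saved every `stride`
integrator substeps, exactly like an MD trajectory's save frequency;
every stored frame then represents a physically decorrelated snapshot
of the fast degrees of freedom.  A divergence guard (|x| > 10³) raises
an error that almost always means the step size is too large for the
stiffest part of the potential.

Potentials: harmonic single wells `(k/2)(x-c)²`; quartic double wells
`h((u/w)² - 1)²` with minima at ±w, crest (height h) at the centre, and
the lower basin labelled "bound" by convention; and a 2D pocket
(Gaussian attractive wells at fixed anchor sites, an optional Gaussian
barrier on the escape route, a harmonic channel in y, and an optional
gentle radial "escape ramp" beyond the pocket rim that models the
entropic drift of a released ligand into bulk — without it a released
particle lingers at the rim of a bounded 2D domain, which no solvated
3D system does).

## Iterative unbinding protocol

Contacts are particle-anchor distances (in general: ligand-protein
heavy-atom distances supplied as a per-frame table).  The protocol
constants follow the published values: inclusion cutoff d_in = 3.5 Å,
removal cutoff d_out = 6 Å, spread cutoff d_var = 1 (interpreted as a
variance threshold in Å²; the source calls the 1 Å value a variance
although it carries length units, so a standard-deviation mode is
available via `var_mode="std"`), per-distance increment d_tar = 1 Å,
force constant k = 20 per Å².  Each iteration biases the sum of the M
active distances toward D = D0 + M·d_tar, ramped linearly over the
iteration (the simplest monotone schedule).  Add/remove rules are
evaluated on the trailing half of each iteration (`evaluation_window`),
matching the "last half of the iteration" reading of the protocol;
removal uses the windowed mean by default ("any frame" mode available).
Iteration lengths are in frames (defaults 10,000/5,000; the toy tests
use 2,000/1,000), replacing wall-clock nanoseconds.  Contacts removed
once never re-enter.  Equivalence groups (anchors interconvertible by an
internal rotation) are user-declared and merged to their unweighted
centre of mass; inferring them automatically would require chemical
topology, which is out of scope.

Termination: the active set empties, i.e. no stable interaction
remains.  On the shipped three-anchor pocket this reliably leaves the
particle beyond d_out of every anchor, and the removal audit (every
removed contact exceeded the mean or variance rule at removal time) is
checkable from the recorded history.

## String refinement and binless WHAM

The unbinding trajectory seeds a string of nodes (default 100 windows)
equidistant in arc length.  Each iteration: sample every window under a
per-CV harmonic restraint at its node (k = 20, default 5,000
steps/window, all windows propagated as one vectorised batch), fit an
order-8 polynomial per CV against the arc parameter through the window
means, re-place nodes equidistantly on the refitted curve, and declare
convergence when every CV's maximal node change is below 7% of that
CV's path range or below 0.3 Å absolute (range-relative reading of the
7% rule; a value-relative switch is not provided because CV values near
zero make it singular).  Tangential drift of window means is absorbed
by the reparametrisation, so a string seeded on the minimum-energy path
passes the convergence test after a single iteration.

Unbiasing uses the binless weighted-histogram equations

    f_i = -kT ln Σ_n m_n exp(-u_i(x_n)/kT) / Σ_j N_j exp((f_j - u_j(x_n))/kT)

solved by self-consistent iteration (gauge f_0 = 0, tolerance 1e-7 on
max |Δf|), with an optional direct likelihood maximisation
(`method="ml"`, L-BFGS with analytic gradient) that the tests check
against the iteration.  Optional per-sample multiplicities turn the
solver into a quadrature evaluator, which is how the two-window
Gaussian closed form is verified to 1e-3 kT.  After convergence the
solver checks that adjacent windows actually overlap (minimum
nearest-neighbour overlap of the window sample distributions > 1e-6)
and raises with diagnostics otherwise — with disjoint windows the
self-consistent equations still "converge", silently, to meaningless
stitched free energies.

The PMF is estimated from the unbiased weights along the normalised
string coordinate (samples projected to the nearest node; binning is
display-level only), shifted to zero at its minimum.  The barrier is
the global maximum minus the bound-side minimum.  Standard errors come
from re-solving WHAM on a contiguous 4-way split of every window's
samples.  TS candidates are the five highest-free-energy windows,
grown as a contiguous block around the global maximum with ties broken
toward the bound state (so a flat profile yields the first five
windows).

## MLTSA

Downhill trajectories are unbiased runs started from TS candidates;
the candidate whose outcomes are closest to 1:1 IN/OUT is the working
TS (ties go to the higher-free-energy candidate).  Labels come either
from the decisive coordinate's final basin (analytical benchmark; a
final value exactly at the crest is assigned IN — any deterministic
rule suffices for a measure-zero event) or from two key monitored
distances (bound if both below 3.5 Å over the final frames, unbound if
either exceeds 6 Å, otherwise flagged unresolved and excluded).

Frames from an early-time window of the training trajectories are
concatenated, shuffled, and split 0.7/0.3 into train/test; a separate
set of trajectories is held out entirely and scored per-trajectory by
majority vote over its window frames (a per-frame validation accuracy
is also reported).  Classifiers are fixed: a single-hidden-layer
perceptron (100 ReLU units, Adam, learning rate 1e-3, ≤500 epochs,
tolerance 1e-4 with 10-epoch patience) and gradient-boosted trees (up
to 500 estimators, learning rate 0.1, Friedman-MSE splits, depth 3,
minimum split 2 / leaf 1).  The GBDT's 0.1 validation fraction drives
early stopping with a 20-round patience — a validation fraction is
inert in scikit-learn without a stopping patience, and stopping
typically ends boosting at 150–300 trees; `patience=None` restores the
fixed 500-tree fit.

Feature relevance uses the global-mean swap: one feature at a time is
replaced everywhere by its mean over the training frames, the model
re-predicts, and the drop is baseline accuracy minus swapped accuracy.
The analysis is model-agnostic; the GBDT additionally reports its
normalised split-gain importances.  In the benchmark replicas the
drops are evaluated on the held-out trajectories: on the shuffled
frame split both models partially memorise trajectory identities, which
masks genuine feature reliance, whereas predictions on unseen
trajectories can only rely on transferable signal.

## The analytical benchmark

The benchmark emulates the downhill construction with 25 independent
1D coordinates observed through 180 linear features:

* one decisive double well (h = 6 kT, w = 1.4, friction 25) started at
  its crest; its final basin defines IN/OUT.  The elevated friction
  makes it the slow mode: by frames 30–60 (of 500, saved every 40
  substeps of dt = 0.005) its sign agrees with the final label ~98% of
  the time — the window is informative but not trivially separable,
  and fewer than ~1–2% of trajectories flip basins after the window;
* a fast noise bath (harmonic wells, stiffness 0.5–2, friction 0.1)
  whose states decorrelate between saved frames;
* persistent "fingerprint" coordinates — twelve low-barrier double
  wells (friction 25) and five slow harmonic wells (friction 40) whose
  values persist across a trajectory.  These give the frame-shuffled
  test split a memorisation channel: the endlessly boosting GBDT
  exploits it nearly fully (test accuracy above 99% against a ~98%
  signal ceiling) while held-out-trajectory accuracy stays
  signal-limited for both models — reproducing the characteristic
  test/validation contrast between the two classifiers.

Features are L1-normalised rows (coefficients read as percentages
summing to 100).  Exactly 11 rows carry the decisive coordinate with
share α stratified over 35–65%: α is the construction's sole
correlation-strength parameter, so correlated rows draw their noise
from the fast bath with weights inverse to each coordinate's
fluctuation amplitude (three terms per row — few enough that different
correlated features carry largely independent noise, which is what
makes a boosted-tree ensemble distribute importance across the top
features instead of concentrating it on one).  The stratification
keeps the α values distinct enough that "the top-k correlated
features" is well defined.  Uncorrelated rows mix 1–4 arbitrary noise
coordinates.  The 5-DW variant uses 5 double wells and 15 correlated
features.

Each replica draws 180 fresh training trajectories plus 50 validation
trajectories from the frozen construction.  Accuracy claims are means
over ≥10 replicas.  What passing benchmarks does **not** show: real
molecular features are nonlinearly entangled, label noise is not
basin-clean, and the memorisation channel of real downhill data has a
different (unknown) strength — the benchmark validates the machinery
and its sensitivity/specificity contrast, not performance on any real
ligand-protein system.

## Kinetics

Eyring-Polanyi with transmission coefficient 1 and CODATA constants
via `scipy.constants`: ΔG‡ = k_B T ln(k_B T/(h k)), and its exact
inverse.  Rates in s⁻¹, barriers in kcal/mol, temperature in K.

## Scope and limitations

All-atom simulations are out of scope: published CDK2 free-energy
barriers (16.29 and 20.27 kcal/mol) and CDK2 classifier accuracies
(80.11% / 93.83%) require real MD trajectories and are not reproduced
here — they remain reference values, with the toy-scale WHAM, string
and unbinding properties standing in as the checkable surrogates.
Likewise out of scope: k_on / binding free energies (the string method
is the wrong tool for fully dissociated states), underdamped dynamics,
force fields, PDB/topology parsing, Voronoi-cell string variants, 2D
PMF surfaces, nonlinear feature mixing, and hyperparameter search.

Problem sizes in the shipped tests (window counts, steps per window,
replica counts) are the package's chosen desk-scale defaults: large
enough that the statistical tolerances quoted above are met with
margin, small enough to run on a single CPU in minutes.
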