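# Methods

This note records the models, conventions and numerical choices behind
`binderscreen`, in the spirit of a methods supplement: what each
computation assumes, which knobs matter, and what the synthetic study
does and does not demonstrate.

## Coordinate model and conventions

Structures are Cα-only. Every screening metric in the package is a
Cα quantity, so side chains, backbone atoms and ligands are never read;
PDB input keeps the first-listed alternate location and rejects insertion
codes (designed models carry neither). Wherever a flat per-residue index
is needed — confidence matrices, prediction payloads — residues are
ordered binder chain first, then target chains in declared order, 0-based.
pLDDT is stored on the 0–100 scale; inputs that look like fractions in
[0, 1] are rescaled with a logged warning.

## Superposition and RMSD metrics

Optimal superposition is the closed-form Kabsch construction (SVD of the
3×3 covariance of centred point sets). Improper (mirror) solutions are
always excluded by flipping the sign of the smallest singular vector when
the raw determinant is negative; the returned rotation has determinant +1
to machine precision even for near-planar sets. At least 3 paired points
are required.

- *Monomer RMSD* pairs residues strictly by order (designed and predicted
  sequences are identical by construction, so no alignment is attempted)
  and reports the post-fit RMSD.
- *Complex RMSD* superposes on target-chain Cα only and evaluates the
  RMSD over the requested scope (`binder_only` or `all_residues`) without
  refitting. Fitting on the target is deliberate: the question the metric
  answers is whether the binder lands correctly *relative to the target*,
  and fitting on binder atoms would hide exactly the placement errors the
  screen is meant to catch. Which residue set the production screen's
  complex-RMSD threshold used is not documented; both scopes are exposed
  and the filter default is `all_residues`.

`pae_interaction` is the average of the two interchain block means of the
predicted-aligned-error matrix (binder→target and target→binder). This
makes the value invariant to transposing the matrix — the orientation
convention of the input never matters — and equal to the grand mean over
all ordered interchain pairs whenever the two blocks have equal
cardinality (they always do: one is the transpose-shape of the other).
Intrachain entries and the diagonal never contribute.

## Filtering

The default screen is `pae_interaction < 10` and `af2_complex_rmsd < 5` Å.
Both thresholds are strict because that is how the screen is written;
strictness and direction are per-criterion options. Designs missing a
required metric fail closed with the metric listed, matching conservative
screening practice: an unscoreable design is not a passing design.

Pareto-front selection is direction-aware non-domination; quota selection
peels whole fronts until the next front would overflow, then admits a
prefix of it ordered by a tie-break metric (default `pae_interaction`
ascending, the most discriminative single metric; design id breaks exact
ties). Top-fraction selection takes the best ⌈fraction·n⌉ with design-id
tie-breaks, so all selections are deterministic.

## SC50 estimation

The titration readout is modelled as a one-site saturable isotherm
`f(c) = f_max · c / (c + SC50)`, chosen over a free-slope logistic
because "half of the expressing cells collected" is literally the
half-saturation point of such an isotherm and the extra Hill parameter is
unidentifiable at typical 6-point titrations (a Hill-slope variant is
available behind `hill_slope=True`). The fit minimises squared residuals
on the fraction scale with the concentration axis parameterised as
log₁₀ SC50 (bounds ±6 decades around the tested range), making the
estimator exactly scale-equivariant on noiseless data.

Collection fractions are frequency ratios against an expression-only
reference sort, rescaled by total collected cell counts when recorded
(plain frequency ratios otherwise) and clipped to [0, 1]. Avidity sorts —
multivalent target presentation used to capture weak binders — are
excluded from fitting because avidity distorts the monovalent
concentration dependence; they serve only as an upstream enrichment gate.
Two guard rails are applied after fitting, both configurable artifact
choices rather than biophysics: maximal observed fraction below 0.1 →
`no_binding`; fitted SC50 beyond 10× the highest tested concentration →
`out_of_range`. (With `f_max ≤ 1`, clean data generated beyond that
window is already caught by the no-binding gate, so `out_of_range` mainly
intercepts noisy fits.) Success calling is strict: status `converged` and
SC50 strictly below 4 μM.

## Efficiency accounting

`efficiency = (n_pass/n_total) / (cpu_s + 100·gpu_s)` per design, with
the 100 CPU-s-per-GPU-s conversion reflecting relative hardware scarcity.
Heterogeneous per-design timings are summed and divided by the total
count, since the quantity is defined per design. ROC analysis requires an
explicit declaration of metric direction (lower-is-better for
pAE_interaction and RMSDs, higher-is-better for pLDDT); there is no
silent auto-flip, and tied scores are grouped into single ROC steps so
ties cost AUC rather than inflating it.

## Synthetic study design

The generators produce every input the screen consumes, with ground truth
known exactly:

- *Toy complexes* are ideal Cα helices (1.5 Å rise, ~100° turn per
  residue, 2.28 Å radius → 3.8 Å consecutive Cα spacing) packed at a
  9 Å axis offset; seeds set phases and sequences.
- *Perturbed predictions* apply a seeded low-frequency sinusoidal
  displacement field plus a linearized rigid jitter to the scoped chains
  and solve the amplitude by root bracketing so the realized
  complex-aligned RMSD matches the request within 2%.
- *Confidence bundles* draw a per-design interface-error center from
  `Normal(mu0 − delta·is_binder, sigma)` (entries scatter ±1.5 Å around
  it, truncated to [0, 31.75] Å — the conventional encoding ceiling of
  predicted-aligned-error outputs) with binder pLDDT declining linearly
  in the center, so confidence metrics correlate the way real predictor
  output does.
- *Sort counts* are binomial draws at the stated depth from a pooled
  cell model (10⁷ cells, 0.5% per-design frequency, 2% background
  collection) whose expected collected fractions follow the isotherm.
- *Benchmarks* combine these per design: labels are assigned exactly
  (`round(n·binder_fraction)` positives), binder-only RMSD targets are
  drawn lognormally (medians 2.5 Å for binders, 9 Å for non-binders) and
  realized by perturbation, and all recorded metrics are *measured* on
  the generated artifacts, so tables regenerate identically from emitted
  files.

Default conditions — `mu0 = 20` Å, `sigma = 4` Å, `delta = 8` Å, 5%
binders, 12/24-residue chains — were fixed so that roughly 2% of designs
clear the default screen, the regime real campaigns operate in. The
acceptance study runs 2000-design benchmarks, a 20-seed SC50 recovery at
depth 10⁵, and 50–100-instance oracle comparisons; these sizes give
stable statistics in seconds on one CPU.

What passing does **not** show: the fixtures have no real protein
geometry beyond a Cα trace, no correlated per-residue error structure, no
target-to-target variability and no energy-score pathologies, so results
certify the screening machinery, not prospective design success on real
targets.

## Pipeline contracts

The prediction request payload carries per-chain sequences, the full
designed Cα coordinates (used to seed the predictor's first recycle in
initial-guess mode), a per-chain template flag (true for target chains)
and a reduced-extra-MSA annotation; it is validated, serializable and
round-trippable, and no inference happens in this package. The
design/relax cycle enforces its stage contracts each iteration — designer
sees the binder masked and must return a same-length sequence; relaxer
must preserve chain topology; target sequences are never modified — and
defaults to 3 cycles (no canonical count exists; 3 is enough for the
alternation to converge on the mock stages while keeping runs cheap).
Shipped designer/relaxer implementations are deterministic mocks;
adapters to real design/relax programs are deliberately out of scope.

## Known limitations

Single-model PDB input only (no mmCIF, ligands or full-atom detail);
no TM-score or coordinate-derived lDDT; no bootstrap intervals on AUC;
the SC50 estimator is stated explicitly here rather than claiming
equivalence to any published pipeline's unpublished normalization.
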