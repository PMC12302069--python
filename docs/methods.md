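# Methods

`redoxlra` computes one-electron oxidation free energies and redox
potentials of small solvated molecules from vertical energy gap (VEG)
ensembles, together with the diagnostics used to judge whether those
ensembles are trustworthy.  This note records the model, the estimators,
the numerical conventions, and what the built-in synthetic data does and
does not establish.

## The physical model

The oxidation `Reduced -> Oxidized + e-` is described along the vertical
energy gap coordinate ΔE = E_ox − E_red, evaluated at fixed nuclei.  With
ensembles sampled on the two end states, the exact free-energy
perturbation (Zwanzig) identities are

    ΔG°_ox = −kB T ln ⟨exp(−ΔE / kB T)⟩_red  (forward, reduced ensemble)
    ΔG°_ox = +kB T ln ⟨exp(+ΔE / kB T)⟩_ox   (reverse, oxidized ensemble)

Truncating the cumulant expansion of either expression at first order and
averaging the two directions gives the linear response approximation (LRA)

    ΔG°_ox = ½ (⟨ΔE⟩_red + ⟨ΔE⟩_ox),    λ = ½ (⟨ΔE⟩_red − ⟨ΔE⟩_ox),

with λ the reorganization energy.  Under linear response both diabatic
free-energy surfaces are parabolas of equal curvature 1/(4λ) along the gap
coordinate:

    G_red(x) = (x − ⟨ΔE⟩_red)² / 4λ
    G_ox(x)  = (x − ⟨ΔE⟩_ox)² / 4λ + ΔG°_ox,

which satisfy the exact construction identity G_ox(x) − G_red(x) = x at
every x; the package asserts this to 1e−10 eV.  The gap spread in each
state obeys the fluctuation–dissipation relation σ² = 2 kB T λ.

Potentials are referenced to the standard hydrogen electrode via
E° = (ΔG°_ox − ΔG°_SHE) / n with ΔG°_SHE = 4.44 eV per electron and n the
electron count (1 throughout).  Because all energies are carried in eV per
transferred electron, the Faraday constant cancels identically and never
appears numerically.

Sign convention: ΔE = E_ox − E_red everywhere, so λ ≥ 0 is the physically
expected ordering ⟨ΔE⟩_red ≥ ⟨ΔE⟩_ox.  A violation is flagged on the
result (`anomalous_lambda`), not raised, since small-sample noise can
produce it legitimately.

## Estimators and uncertainty

**Exponential averaging is ill-conditioned in the condensed phase.**  The
forward exponential estimator is dominated by configurations near
ΔE ≈ ⟨ΔE⟩ − σ²/kBT, which sit σ/kBT standard deviations into the tail of
the sampled distribution.  Aqueous reorganization energies of ~1 eV at
310 K give σ ≈ 0.23 eV ≈ 8.7 kBT, so the sample log-mean-exp is controlled
by the single most extreme draw and is biased by several tenths of an eV
at any affordable sample size.  This is the standard convergence failure
of one-sided free energy perturbation, and it is why LRA is used in this
regime at all.  `zwanzig_free_energy` therefore offers two evaluations:

* `method="exponential"` (default): the literal log-sum-exp estimator,
  overflow-safe to |ΔE|/kBT ≈ 400.  Trustworthy when σ ≲ a few kBT.
* `method="gaussian"`: the second-order cumulant evaluation
  m̂ ∓ s²/(2 kB T) from the sample mean and unbiased variance, exact for
  Gaussian gap distributions and the appropriate form when σ ≫ kBT.

The estimator consistency checks use the Gaussian evaluation at λ = 1 eV
(where the exponential form cannot converge) and the exponential form in
the well-sampled small-λ regime.  Even the Gaussian directional estimate
carries appreciable measurement noise through its variance term: at
n = 500 the standard error of s²/(2kBT) alone is ≈ 0.06 eV per replicate,
so averages over ~50 replicates determine the bias only to ≈ ±0.01 eV.

**Bootstrap.**  Uncertainty on ΔG°_ox comes from paired within-state
resampling: `n_boot` (default 1000) resamples of each state's gap vector,
percentile 2.5/97.5 interval, explicit seed.  The interval is clamped to
contain the point estimate (relevant only for degenerate data).  Coverage
was verified at ~95% on synthetic ensembles, and the interval width
scales as 1/√n as expected.

## Convergence diagnostics

* **Running average**: cumulative mean of the gaps in frame order; its
  final element equals the ensemble mean to 1e−12 relative.
* **Histogram modality**: bins of width 0.05 eV (configurable) spanning
  the data range, smoothed with a 3-bin moving average; modes are strict
  local maxima of the smoothed counts.  A mode must additionally reach 5%
  of the tallest smoothed peak — without this floor a single stray sample
  in an otherwise empty tail bin registers as a second mode, which no
  practitioner would accept from a histogram of 500 samples.  Converged
  sampling should show a single peak per state.
* **Conformation–gap decorrelation**: solute coordinates of every frame
  are rigid-body aligned to the first frame (centroids removed,
  least-squares rotation by the orthogonal Procrustes/Kabsch solution,
  no mass weighting, hydrogens included), PCA is taken over the aligned
  coordinates, and |Pearson ρ| is reported for PC1 vs gap, PC2 vs gap,
  and PC1 vs PC2.  Uncorrelated values (|ρ| small) indicate the frames
  behave as independent draws.  Zero conformational variance reports
  ρ = 0 by convention.

## Solvation structure

g(r) is computed between two role/element selections (default: pooled
solute heavy atoms as references, water oxygens as targets) with
minimum-image distances in the cubic box, bin width 0.05 Å, r_cut 10 Å
(must not exceed L/2), normalized by the ideal-gas shell expectation
N_ref · frames · ρ · (4π/3)[(r+dr)³ − r³].  The counterion is never part
of the target selection.

First-shell reduction is deliberately rule-based because peak integration
of a structured RDF is ambiguous: after 3-bin smoothing, r_max is the
first strict local maximum with g > 1, r_min1 the first strict local
minimum after it, and n_wat = 4πρ Σ g r² dr over bins up to r_min1.  If
the tail shows no strict minimum the integration runs to the end of the
profile, and a profile with no qualifying peak is returned flagged
undefined rather than given fabricated values.

Counterion placement is audited by binning frames on the minimum-image
distance between the solute center of mass (standard atomic masses) and
the single ion, default edges 10 and 20 Å (bins r < 10, 10 ≤ r ≤ 20,
r > 20), with per-bin mean gaps.  Statistically indistinguishable bin
means indicate the ion's position does not bias the gap ensemble.

## QM-region construction

A region spec is a criterion plus radius.  Water membership is decided
solely by the water oxygen (hydrogens follow their oxygen; molecules are
never cut): `com` selects waters whose O lies within the radius of the
solute center of mass, `atom` within the radius of any solute atom; ties
at exactly the radius are included.  Radius 0.0 is the sentinel for a
solute-only region.  The counterion is never promoted to QM.  Everything
outside the region becomes a fixed point charge from the charge set of
the requested oxidation state, so every atom is in exactly one of the QM
set or the MM charge list.  By construction the atom-criterion selection
is a superset of the com-criterion selection at equal radius, and
selections are nested under increasing radius; both properties are
asserted in the tests.  The default sweep covers radii 0.0 and 4.0–7.5 Å
in 0.5 Å steps.

`surrogate_gap` supplies a stand-in gap for pipeline exercises:
ΔE = ΔE_gas + Σ k_e (q_i^ox − q_i^red) q_j / r_ij over solute atoms i and
MM charges j (k_e = 14.399645 eV·Å/e², minimum image, clash error below
0.5 Å).  It is a fixed-charge Coulomb coupling with no polarization,
exchange, or charge transfer; it reproduces qualitative trends (the
environment term weakens as the QM region grows, vanishes for an
uncharged solute) and must never be read as a quantum-level gap.

## Synthetic data: what it emulates and what it does not

`generate_gap_ensembles` draws the two state ensembles from the exact
linear-response generative model: Normal(dG ± λ, σ²) with σ² = 2 kB T λ,
T = 310 K, 500 samples per state by default — matching the end-state
sampling depth typical of gap-based redox studies.  A skew option draws
from a skew-normal reshaped to the same mean and variance for robustness
checks.  `generate_solvated_box` builds a 50 Å cubic box (default) with a
rigid idealized solute template at the center, TIP3P-like rigid waters
(O–H 0.9572 Å, H–O–H 104.52°, charges −0.834/+0.417) placed by seeded
rejection sampling with a 2.4 Å heavy-atom exclusion, and an optional
single counterion at least 3 Å from the solute.

Deliberate non-features: frames are independent draws with no time
correlation (the decorrelation diagnostic is what justifies treating real
frames that way); water placement carries no attractive structure, so
g(r) is flat rather than peaked at contact; template geometries are
regular polygons with 1.4 Å bonds and the charge sets are hand-assigned
stand-ins whose only guaranteed properties are the exact formal sums
(reduced total = formal charge, oxidized = formal + 1 spread over heavy
atoms).  Consequently, passing tests establish the correctness of the
estimators, selections, and bookkeeping — not the realism of any force
field or electronic structure.  Template names are deliberately
geometric (`ring6`, `ring6-OH`, `ring6-O-`, `ring9`, `tricycle`).

Test and acceptance problem sizes were chosen to keep the full suite in
the tens of seconds while leaving statistical headroom: boxes of
~120 waters at L = 25 Å over 10–50 frames, gap ensembles of 500 samples
per state, 50–200 replicates for bias/coverage measurements.

## Numerical conventions

* Units fixed package-wide: Å, eV, elementary charges, K; kB =
  8.617333262×10⁻⁵ eV/K; no unit autodetection.
* Minimum image: each displacement component wrapped into (−L/2, L/2];
  cubic boxes only, non-cubic input is an explicit unsupported-feature
  error.
* Atom indices are 1-based in all emitted files; internal order is file
  order.  XYZ files carry the box edge as a `box=<L>` comment token;
  roles and the two charge sets travel in a comma-separated topology
  sidecar written at full precision (rounding the charges could break the
  exact formal-sum invariant).
* Charge bookkeeping tolerance 1e−6 e; the +1 oxidation constraint is
  enforced only when the solute actually carries charges (minimal PDB has
  no charge fields, so PDB-derived snapshots are charge-free and exempt).
* Gap tables are CSV with header `frame,state,cutoff,gap_eV`, written at
  6 decimals; (frame, state, cutoff) keys must be unique.
* Bootstrap, box generation, and gap generation consume explicit seeds
  through `numpy.random.default_rng`; the CLI refuses to run `simulate`
  without one.

## Known limitations

* No estimator beyond first-order truncation (no BAR/MBAR, no
  higher-order cumulants) — the half-sum LRA is the point of the package.
* The Coulomb surrogate cannot reproduce quantum gaps; real applications
  must supply gap tables from their own electronic-structure pipeline.
* Minimal PDB support only (no occupancy/altloc/chains); no binary
  trajectory formats.
* Single counterion only; no ionic-strength ensembles.
* First-shell reduction is sensitive to the stated smoothing and
  extremum rules near-threshold; the rules are fixed rather than
  adaptive precisely because the reduction is ambiguous.
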