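# Methods

This note documents the models, parameter choices and numerical decisions
behind `presans`, and what the synthetic-data experiments do and do not
demonstrate.

## PRE quantification

Peak heights are derived from fitted Lorentzian volumes as
I = V/(LW_H·LW_C). Ratio errors use first-order propagation from the
spectral noise s.d.; a non-positive paramagnetic height is treated as a
fully broadened peak: the ratio is floored at 0, the noise s.d. stands in
for |I_para| in the error, and the methyl is routed to the near class.

The intensity-ratio relation ties the ratio to the PRE rate through both
the exponential loss during the τ_HMQC = 7.7 ms constant-time ¹H period and
the Lorentzian height reduction of the ¹H single-quantum and ¹H–¹³C
multiple-quantum coherences, whose diamagnetic rates R₂ᴴ and R₂ᴴᶜ are fit
per methyl from mono-exponential decays (unweighted nonlinear least squares,
log-linear initialisation; a rate converging to 0 is flagged as a boundary,
not an error). The relation is strictly decreasing in Γ₂ and equals 1 at
Γ₂ = 0, so the inversion uses Brent root search on an expanding bracket
(relative tolerance 10⁻¹⁰). Ratios ≥ 1 mean no resolvable broadening and
return Γ₂ = 0 with a warning.

Methyls in the quantitative band that lack their own relaxation rates fall
back to the dataset median rates (logged); with no rates anywhere they are
marked `unusable` and excluded.

### The constant K

The Solomon–Bloembergen conversion d⁶ = (K/Γ₂)(4τc + 3τc/(1+ω²τc²)) needs
the electron–nucleus prefactor K. The protocol this package
operationalises prints K = 1.233×10⁻²³ cm⁶s⁻², which is about 10⁹-fold
larger than the standard nitroxide–¹H value of ~1.23×10⁻³² cm⁶s⁻² and,
taken at face value, maps typical methyl PRE rates to distances of several
hundred Å — inconsistent with the 2–24 Å restraint bands the same protocol
prescribes. We deliberately do not silently "fix" the printed value:
both are shipped as named constants (`K_PRINTED`, `K_SOLOMON_BLOEMBERGEN`),
K is a required and logged configuration item, and every computation that
needs absolute distances states its K explicitly. The synthetic generator
uses the standard value so that its geometry, rates and restraint bands are
mutually consistent.

ω is the proton Larmor *angular* frequency, 2π × spectrometer frequency;
the default field is 850 MHz. At τc = 81 ns, ωτc ≈ 430, so the dispersive
spectral-density term is negligible and the conversion is insensitive to
this convention at the ~10⁻⁵ level.

### Restraint construction

Restraints anchor at the tagged residue's Cβ and the methyl carbon.
Class boundaries follow the ratio strictly: r < 0.2 → (2, 18) Å,
r > 0.8 → (24, 99) Å, r exactly 0.2 or 0.8 → quantitative. Quantitative
bounds are d ± (σ_d + 6 Å) with the lower bound floored at 2 Å (hard-sphere
contact). The ±6 Å absorbs the length and flexibility of the tag linker —
i.e. the offset between the electron and the Cβ anchor.

### τc calibration

The electron–nucleus correlation time is refit from reference PREs by
minimising Σ((Γ₂ᵒᵇˢ − Γ₂ᶜᵃˡᶜ)/σ_Γ)², where Γ₂ᶜᵃˡᶜ uses ⟨r⁻⁶⟩ averaging over
a discrete, weighted tag-conformer cloud. τc is log-parameterised; cloud
weights live on the simplex via a softmax; optimisation is Nelder–Mead
(dimensions are small), and the standard error comes from the numerical
curvature of the profile χ² along log τc with the weights re-optimised.
The cloud (default: a single point, or 32 points uniform in a 5–9 Å shell
around the Cβ, fixed seed) is a desk-scale surrogate for full tag-rotamer
dynamics, and the 1/σ_Γ² weighting approximates observed-σ error weighting;
both are deliberate simplifications of the cited ensemble-optimisation
protocols.

## SANS back-calculation

Candidate structures are reduced to one bead per residue at the Cα
(geometric centre if absent). Each bead's excess scattering length sums the
residue's heavy atoms, its non-exchangeable hydrogens (deuterated per the
chain's growth-labelling fraction), its exchangeable hydrogens (deuterated
as f_D2O × 0.9 exchange efficiency, configurable), minus the solvent
scattering-length density — linear in f_D2O between H₂O and D₂O — times the
residue volume. Compositions use ionisation states expected near neutral pH
and consensus residue volumes; b(H) = −3.739 fm and b(D) = 6.671 fm are
fixed physical constants of the tables. 70% deuteration is modelled as
uniform fractional deuteration of non-exchangeable hydrogens, matching
fractional-D₂O growth labelling.

This residue-bead model deliberately omits the hydration shell and atomic
detail of full atomic-form-factor calculators. The pipeline's contracts —
χ² ranking, normalisation, consensus fitness, contrast matching — are
insensitive to that level of detail, which is why a coarse-grained
calculator suffices for selection; absolute χ² values against real data
would not be comparable to an atomic calculation.

Intensities use the exact Debye double sum with the i=j and q→0 sinc limits
handled analytically, so I(0) = (Σb)² identically. χ² fitting interpolates
the model onto the experimental q grid, fits a scale factor in closed form,
and divides by N−1 (a flat background term is available behind a flag but
off by default, matching scale-only fitting conventions). Curves are read
and written as whitespace 3-column text (q, I, σ) with `#` comments; q in
Å⁻¹, with nm⁻¹ conversion available.

Per-dataset χ² values across a candidate set are min–max normalised to
[0, 1]; an all-equal set maps to zeros with a warning. The consensus
fitness is the plain sum of normalised χ² over however many datasets the
configuration lists.

## Selection protocol

Restraint violation energy is a flat-bottom quadratic,
E = Σ max(0, d−upper, lower−d)², with unit weights. Docking engines often
use a soft-square form with a linear tail; the quadratic is simpler and
order-preserving for moderate violations, and a linear-tail variant is
available (`form="soft-square"`). ln(E + 10⁻¹²) guards E = 0.

Low-energy outliers use the box-and-whisker rule on ln E with
linear-interpolation (type-7) quantiles and a whisker of 2×IQR, low side
only. Type-7 quantiles are pinned for cross-implementation determinism.

Orientational RMSD superposes two structures on the backbone of the fixed
(reference) chains and measures backbone RMSD over the mobile chains with
no second fit. Clustering defaults to the `reference` mode: o-RMSD of every
candidate to the best-fitness structure, grouped by 1-D single linkage with
a 5 Å gap threshold (no cutoff is prescribed by the protocols this
operationalises; 5 Å separates docking basins at the decoy scales used
here). A `pairwise` complete-linkage mode on the full o-RMSD matrix is also
provided. Clusters are ranked by mean member fitness (ties: larger cluster,
then label order). The final ensemble keeps members of the top cluster
whose fitness is strictly better than the minimum fitness in the
second-ranked cluster — "better than any member" is read as better than
that cluster's best. A single cluster selects all members with a warning.
The centre is the member with the lowest mean backbone RMSD to all members
(self included); ties go to the earliest id.

Superposition itself is the closed-form SVD least-squares rigid fit with
reflections forbidden; collinear selections are rejected as
underdetermined.

## The synthetic study

`make_toy_complex` builds a ring of pseudo-helical chains (backbone
N/CA/C/O, Cβ and one methyl carbon per residue, isoleucine stubs) around a
central cavity, with Cβ/methyls facing the ring interior where the
inter-chain interface lies, plus 0.05 Å coordinate jitter; everything is a
pure function of (parameters, seed). Default study conditions: 3 chains ×
30 residues; tag on chain A residue 15 with the electron 6 Å beyond the Cβ
pointing away from the complex (a solvent-exposed nitroxide tether); τc =
81 ns at 850 MHz; diamagnetic rates R₂ᴴ ~ U(40, 70) s⁻¹ and R₂ᴴᶜ ~
U(60, 100) s⁻¹, appropriate for a complex in the hundreds of kDa; additive
spectral noise of 2% of the mean diamagnetic height; SANS curves on
q ∈ [0.01, 0.30] Å⁻¹ (48 points) with 3% fractional Gaussian noise, two
contrasts that each nearly match out one labelling state (perdeuterated
chains in 0% D₂O; the protonated mobile chain near its ~42% D₂O match
point). Decoys perturb the mobile chain by a translation of uniformly drawn
magnitude in [0.5, 1.5]×20 Å and a rotation of [0.5, 1.5]×45° — the spread
of rigid-body docking candidates, which does not pile decoys onto the true
pose.

With these conditions the ground truth satisfies its own restraints to
within the noise (E_exp ≈ 0 against decoy energies of 10²–10⁴), is flagged
by the 2×IQR rule, wins the consensus fitness, and is selected — in ≥95%
of seeds in the acceptance suite (50 studies of 100 candidates each, ~1 s
per study on one CPU).

What the synthetic data do **not** emulate: side-chain chemistry and real
tag rotamers, correlated/systematic NMR noise, peak overlap and
misassignment, instrument smearing and buffer-subtraction artefacts in
SANS, interface flexibility in the candidates (decoys are rigid), and
hydration-shell scattering. Passing tests therefore demonstrate the
correctness and statistical behaviour of the algorithms, not performance
on experimental data.

## Numerical conventions

Coordinates and distances in Å (the Solomon–Bloembergen step evaluates in
cm and converts, ×10⁸); rates in s⁻¹; times in s in code, ns in user-facing
τc configuration; q in Å⁻¹. Report CSVs format floats to 6 significant
digits, making repeat runs with identical config + seed byte-identical.
PDB I/O follows wwPDB v3.3 columns via gemmi; altlocs keep the
highest-occupancy location (ties: first encountered); HETATM records are
parsed but excluded from named selections; hydrogens are not required
anywhere — the SANS bead model accounts for them compositionally.
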