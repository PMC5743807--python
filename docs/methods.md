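# Methods

## Scope and model

`chemocal` treats a carbon-limited chemostat at steady state: the specific
growth rate equals the experimental dilution rate (μ = D_exp), and every
steady state is summarized by a signed rate vector
(μ, q_S, q_O2, q_CO2, q_X) with uptake negative.  Units are
mmol gDCW⁻¹ h⁻¹ for exchange rates, Cmmol gDCW⁻¹ h⁻¹ for q_X, h⁻¹ for μ.
No correction is made for biomass in the off-gas or for gas-phase
humidity/inerts; those belong to the analytics upstream of this package.

Flux balance analysis is an LP: maximize/minimize one reaction flux subject
to S·v = 0 and bounds, solved with HiGHS (scipy.optimize.linprog) at
primal/dual tolerances of 1e-9.  Optimal solutions are asserted to satisfy
steady state and bounds within 1e-6.  Only the optimal objective value is
treated as reproducible; individual fluxes of degenerate optima are never
asserted except on the toy network, whose optimum is unique.  The biomass
reaction is scaled so its flux is μ (it consumes precursors per gram DCW
formed), which makes the ATP coefficient directly the growth-associated
maintenance (GAME, mmol ATP gDCW⁻¹).

SBML I/O goes through cobrapy (Level 3 + FBC on write; the reader tolerates
legacy note-encoded bounds and falls back to a biomass-named reaction when
no FBC objective is set).  cobrapy also serves as an independent
cross-check of the LP optimum in the test suite, never as the solver.

## Reconciliation and the h test

Measured vectors are adjusted by weighted least squares onto linear
conservation constraints E·x = b with diagonal covariance F = diag(sd²):

    x̂ = x − F·Eᵀ(E·F·Eᵀ)⁻¹(E·x − b),   h = εᵀ(E·F·Eᵀ)⁻¹ε.

h is χ² with rank(E) degrees of freedom under random errors only; data pass
at 95% confidence iff h ≤ χ²₀.₉₅ (α = 0.05 by default, overridable).
Covariance is taken diagonal because only per-quantity SDs are available.

For rate vectors the default constraint set is the carbon balance and the
degree-of-reduction (electron) balance, with γ per mole computed as
4C + H − 2O − 3N + 6S (ammonia as N source, so NH₃ and H₂O carry zero):
glycerol 14, methanol 6, O₂ −4, biomass ≈ 4.0 per C-mol.  When the biomass
carbon content is known, μ joins the system through the definitional row
q_X = μ·C_content, so the growth rate is reconciled too.  Reconciliation is
per steady state; whether to pool a series is left to the caller.

For compositions the constraints are mass closure (macromolecular fractions
sum to 100%) and, per element, consistency between the CHNOS content
implied by the macromolecule monomer formulas and the measured elemental
fractions.

Relevant numerical choices: E·F·Eᵀ condition numbers above 1e12 raise a
"redundant balances" error; the h test with zero residual returns exactly
h = 0; reconciled uptake rates are clamped to the physical sign.

## Biomass composition and equation

Averaging across growth rates uses 1/SD weights per component (falling back
to unweighted means, with a warning, when SDs are missing).  The reported
combined SD is the weighted sample SD around the weighted mean, floored by
the SD of the mean itself — this choice best matches how replicate
compositions of this kind are usually summarized.  Macromolecular averages
are renormalized to sum to exactly 100.

Ash is 100 − (C+H+N+O+S).  The C-mol formula CH_xO_yN_zS_w comes from mole
ratios of the mass fractions; carbon content is 10·C%/12.011 mmol C/gDCW.

The biomass equation fixes exactly 1 g of matter per gDCW: polymer classes
(protein, RNA, DNA, carbohydrate) consume free monomers and release one
water per residue (chain termini neglected — a <0.5% mass effect at
biological chain lengths); carbohydrate uses the anhydroglucose unit
(162.14 g/mol); lipid classes are consumed as intact representative species
(triolein, oleate, ergosterol, tetraoleoyl-cardiolipin, dioleoyl-PA/PC/PI/PS)
mass-weighted within the lipid fraction; sulphate and structural water
enter as such; metals are carried as a mass share and mapped to a model
ion/ash pseudo-metabolite only if the caller provides one.  Measured Asx/Glx
pairs are split 50/50 between acid and amide forms (acid-hydrolysis
convention), PI/PS likewise.  DNA base composition defaults to 41% GC
(configurable).  Total consumed mass is validated to 1.000 g ± 0.5%.

The packaged monomer profiles are **synthetic defaults** — literature-
typical yeast amino-acid, RNA-base and lipid-class profiles (see
`data/default_monomer_profiles.synthetic.tsv`) — because the measured
profiles behind the published compositions are not redistributable.
Consequences: element fractions per macromolecule (notably protein N and S)
differ a little from the original lineage's constants, so reconciled
compositions and the built equations reproduce the published average
columns only approximately.  The elemental-closure check (implied CHNOS of
a built equation within 3% per element) is performed against the
*reconciled* composition, where it holds by construction of the element
constraints; building from unreconciled compositions can leave percent-level
sulfur/nitrogen mismatches that trace to the profile defaults, not to the
bookkeeping.

On the published per-growth-rate table, 1/SD-weighted averaging reproduces
the printed average columns within ±0.5 w/w % for all components except RNA
and structural water; no positive weighting of the printed per-D values can
reach the printed RNA average (the smallest-SD value lies far below it), so
we treat those two columns as products of an averaging/reconciliation step
whose inputs are not fully printed, and make no attempt to tune our
constants to match them.

## Maintenance energies

Pirt's law |q_S| = μ/Y_max + m_s is fitted by ordinary least squares of
|q_S| on μ (the published-table analyses use exactly this).  An optional
weighted fit (1/sd(q_S)²) exists for data with explicit heteroscedastic
SDs; the synthetic-data recovery pipeline uses it because simulated
measurements carry known SDs and the intercept is otherwise the noisiest
quantity in the whole workflow.  The low-growth condition at D = 0.035 h⁻¹
on glycerol is excluded from both the Pirt fit and the GAME calibration by
default (a metabolic shift at very low growth rates moves q_O2/q_CO2 off
the linear trend and roughly halves the apparent maintenance); the
exclusion is a flagged, overridable argument.

NGAME: fix growth to zero and substrate uptake to −m_s, maximize the ATPM
(ATP hydrolysis) flux; the optimum is the ATP turnover sustainable from the
maintenance substrate stream and is installed as the ATPM lower bound.

GAME: golden-section search of the biomass ATP coefficient on [0, 500]
mmol gDCW⁻¹ (coarse 21-point scan first, which also checks unimodality and
tightens the bracket), minimizing the unweighted sum of squared μ residuals
with q_S fixed per condition; convergence when the bracket is narrower than
0.01 mmol gDCW⁻¹.  Fitting μ residuals at fixed q_S is equivalent to
fitting biomass–substrate yields up to weighting.

Validation either fixes μ and minimizes |q_S| or fixes q_S and maximizes μ;
the overall deviation is the mean absolute relative deviation over the
substrate/gas rates, reported as a percent.  Infeasible conditions are
reported per row, never raised.

## Synthetic data

The toy network (glycerol-like substrate C₃H₈O₃) has lumped catabolism
(S + 3.5 O₂ → 3 CO₂ + 18 ATP), anabolism (S + 2 ATP → P), a biomass
reaction (11.65 P + g ATP → X) and an ATPM sink, so FBA has the closed
form |q_S| = (p + (g + e·p)/k)·μ + m/k, with RQ fixed at 6/7 and biomass
carbon content 3p = 34.95 Cmmol/gDCW (C-mol formula CH₂.₆₇O, γ = 14/3).
Defaults (p = 11.65, k = 18, g = 70, m = 2.5) put the simulated series in
the glycerol range of real yeast chemostats: yield ≈ 0.6 g/g, Pirt
intercept ≈ 0.14 mmol gDCW⁻¹ h⁻¹.  The default dilution-rate grid is
0.035–0.160 h⁻¹, six levels.

Noise is multiplicative Gaussian with CV 2% by default (matching the ~1–2%
relative SDs of HPLC and dry-weight analytics), seeded and reproducible;
SD columns carry cv·|value|.  A gross-error injector adds a chosen number
of SDs to one cell and records provenance.  What the generator does *not*
emulate: transients, correlated measurement errors, day effects between
chemostat series, composition drift with growth rate, or secretion of
by-products — so passing recovery tests demonstrate estimator correctness
under the stated error model, not robustness to structured real-world
error.

Under this model the full pipeline (per-steady-state reconciliation →
weighted Pirt fit → ATP-turnover maximization → GAME fit) recovers the true
parameters exactly at zero noise and with a median absolute error below 5%
at CV 2% (20-seed batteries); reconciliation is what makes the intercept
estimable — raw OLS on six noisy points has ~25% intercept SD.

## Known limitations

- Single-objective LP only: no FVA, gene deletions, MILP or thermodynamic
  constraints.
- Gross-error detection stops at the h test; serial elimination to localize
  the faulty measurement is out of scope.
- The monomer constants table is a reviewed but generic yeast set; for
  organism-grade biomass equations supply measured profiles.
- Calibration against a real genome-scale model requires that model's SBML
  (see README) plus its exchange/ATPM identifiers; the package ships only
  the toy network.
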