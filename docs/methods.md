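# Methods

## Scope and data model

`mixtriage` operationalises a tiered triage of formulated
plant-protection products (PPPs). Its inputs are plain CSV tables:
a substance registry (active substances and co-formulants, with optional
CAS and SMILES), product compositions with annual sales, three kinds of
in-silico prediction tables (binary statistical alerts per sub-model,
ordinal expert likelihoods, ADME substrate/inhibitor calls with an
applicability-domain flag and a confidence), and long-format
dose-response viability tables. Mass quantities are stored internally as
fractions in [0, 1]; every file interface speaks percentages, the unit
in which formulation recipes are written. Concentrations are mg/L
throughout; no molar conversion is attempted because several
co-formulants (solvent naphtha, vegetable-oil derivatives) are UVCBs
without a defined molar mass.

## Co-formulant eligibility filtering

Structure-based prediction tools need one discrete structure per query,
so the registry is reduced before scoring: active substances are set
aside, substance classes (polymers, minerals, natural extracts — marked
by an explicit `is_class` column, since no reliable rule can infer
class-ness from a name or a missing SMILES) are excluded, entries
without SMILES are excluded, and duplicates are collapsed. The
deduplication key is the CAS number when present, otherwise the exact
SMILES string; the first-seen entry of a group is kept. The filter is
total (every input lands in exactly one of eligible/excluded, with a
machine-readable reason) and idempotent. Substances excluded here remain
in the sales stream — exposure relevance does not require a structure.

## Two-source organ-toxicity scoring

Statistical and expert systems err differently, so one point is awarded
per source: `statistical_hit` when at least one of the endpoint's binary
sub-models (4 for hepatotoxicity, 6 for nephrotoxicity) alerts, and
`expert_hit` when the likelihood is in {certain, probable, plausible,
equivocal}. The nine-level likelihood vocabulary is totally ordered;
"nothing to report" (no knowledge) scores like a negative but is kept
distinct in output payloads for audit. When a substance/endpoint has
several expert sub-calls the maximum level is used. A missing source
contributes 0.

Content thresholds are strict (`>`): score 2 fires above 0.1 % product
mass, score 1 above 10 %. Score 2 takes precedence when both could fire.
Nephrotoxicity scores are computed but excluded from prioritisation by
default — statistical nephrotoxicity suites are too insensitive (about
50 % on their training data) to justify testing decisions — and can be
re-enabled via `endpoints_included`.

## Toxicokinetic pairing

The pairing rule captures the classical interaction motif: an inhibitor
and a substrate of the same enzyme/transporter in the same product.
Targets are the five major CYP isoenzymes and P-gp. A co-formulant
qualifies as inhibitor when in scope, confidence strictly above 0.5, and
present above 0.1 % (`frac_min`, configurable — treating the observed
"flagged co-formulants always exceeded 0.1 %" regularity as a filter);
an active substance qualifies as substrate when in scope with confidence
above 0.5, optionally restricted to an injectable hepatotoxic-AS list
(by default all AS in the landscape, since the external cumulative
assessment group list is not distributed with the package). One call is
emitted per (product, target), listing all qualifying pairs.

## Sales ranking

Annual co-formulant sales are `product sales (kg) × mass fraction`,
summed over products and aggregated by CAS (CAS-less substances
aggregate by id). Ties break by key lexicographic order so ranking is
deterministic. Products containing a top-`n` (default 10) co-formulant
receive a `top_sales` call carrying the rank.

## Dose-response models and fitting

Viability curves are fitted with two four-parameter families sharing
parameter semantics — `a` response at zero dose, `a·c` asymptote,
`b` dose scale (mg/L), `d` shape:

* exponential: `y = a·[c − (c−1)·exp(−(x/b)^d)]`
* Hill: `y = a·[1 + (c−1)·x^d/(b^d + x^d)]`

The Hill form is written so that its parameters mean the same as the
exponential model's, which keeps the concentration-addition construction
below model-agnostic. Fitting is unweighted least squares on the natural
% scale (independent Gaussian residuals; no variance model is assumed,
and fitting the log-response instead would change little at the noise
levels considered but is not what viability plates report).
Initialisation is a deterministic 8-point grid — `a` at the control
mean, `b` at the geometric mean of positive doses, `c ∈ {0, 0.25}`,
`d ∈ {0.5, 1, 2, 4}` — with the best residual sum of squares winning;
bounds keep `b, d` positive and `c ∈ [0, 5]`. Convergence is reported
honestly from the optimiser. At least 5 distinct positive
concentrations are required (4 parameters + 1); all-constant responses
raise a degenerate-fit error.

Model choice uses `AIC = n·ln(RSS/n) + 2k` (Gaussian, constant dropped;
RSS floored at the smallest positive float so exact interpolation does
not produce −∞); exact ties prefer the exponential model. Selection is
invariant to input order.

The EC50 is defined against the zero-dose response (50 % of control), as
is usual for viability data; it exists only when `c < 0.5` and has
closed forms in both families (`x = b·(−ln((c−0.5)/(c−1)))^(1/d)` for
the exponential), cross-checked against bisection in the tests. The 4PL
(`Bottom`, `Top`, `LogIC50`, `HillSlope` on log10 concentration) is kept
separate for enzyme-inhibition assays, where the midpoint-IC50
convention of plate-reader software applies; zero-dose controls cannot
be log-transformed and are excluded from that fit.

## Concentration addition and the deviation call

Mixture components are fitted jointly with shared `(a, c, d)` and
per-component `b_i` (parallel curves / constant relative potency — the
covariate-style construction of benchmark-dose software). Whether the
shape `d` should be shared is genuinely open; sharing all of `(a, c, d)`
is the choice made here because the CA curve is then exactly a member of
the same family, with potency `b_mix = 1/Σ(π_i/b_i)` for dosed mass
fractions `π_i`. A general Loewe solver (numerical inversion of
arbitrary monotone component curves, `D = 1/Σ(π_i/ED_i(level))`) is
retained purely as an independent oracle; for parallel curves the two
agree identically, which the tests exercise at 21 response levels.

Deviation from additivity is the model deviation ratio
`MDR = EC50_predicted / EC50_observed`. The default decision threshold
of 2 (configurable) operationalises the visual left-shift/right-shift
judgement of dose-addition plots and is the customary MDR cut-off in
mixture toxicology; calls are `more_than_additive` above it,
`less_than_additive` below its reciprocal, otherwise `additive`.
Bootstrap confidence bands for the MDR are deliberately out of scope in
this version (a config hook exists in spirit; the classifier is a point
decision).

## Synthetic data: what it emulates and what it does not

The generator produces a landscape at the real scale by default (1603
products, 1048 co-formulant entries, 185 active substances) with
configurable SMILES availability (0.65), duplicate-CAS rate (0.10) and
substance-class rate (0.15) — chosen so the eligible set lands near the
~490 unique structure-bearing co-formulants of the real landscape.
Prevalences of true statistical/expert positives (hepatotoxicity
0.22/0.07, nephrotoxicity 0.10/0.16) and per-target inhibitor/substrate
rates echo the alert counts the commercial tools report at that scale.
Sales are log-normal in kg (μ = 8, σ = 2 in log-space) so a few bulk
co-formulants dominate, as in the published top-10 table. Composition
fractions come from Dirichlet splits (α = 0.5) of a product's
co-formulant mass, giving both trace (< 0.1 %) and dominant (> 10 %)
entries.

Prediction tables flag each true positive with probability
`sensitivity` and each true negative with probability `1 − specificity`
(out-of-scope marking is applied to true-negative ADME rows only, so the
applicability domain never hides a true interaction). With both set
to 1 the tables equal the truth, and the engine must recover the
generator's per-trigger product sets exactly — that is the end-to-end
test. Passing it shows the rule engine is faithful to its own rules on
realistic table shapes; it says nothing about the accuracy of any real
QSAR/ADME tool, which the package deliberately treats as opaque input.

The default mixture study uses two parallel exponential components
(shared `a = 100, c = 0, d = 2`; `b = 10` and `40` mg/L, mixed 1:1 by
mass, hence `b_mix = 16`), an 8-point geometric dose design spanning
`b/16 … 16b` with 3 technical replicates plus 3 zero-dose controls, and
Gaussian noise of 5 % viability — the design of a typical 96-well
cytotoxicity experiment. Synergy is a potency multiplier `s` on the
mixture's effective dose (a minimal stand-in for a toxicokinetic
interaction raising the internal dose), not a response-surface
interaction term; its analytical transparency (true MDR = `s`) is the
point. Real mixture deviations need not follow this mechanism, so the
power figures measured on synthetic data (detection of `s = 3` in
≥ 90/100 noisy runs; ≤ 10/100 false calls under `s = 1`) characterise
the classifier under this model only.

## Problem sizes and numerics

Seeded studies use 100 runs (parameter recovery, synergy power), 1000
random parameter draws (EC50 closed form vs bisection), and a
full-scale landscape for truth recovery; the whole acceptance script
completes in well under a minute on one CPU. Optimiser tolerances are
1e-13 (xtol/ftol/gtol) so noiseless fits recover parameters to ~1e-9;
root finding uses Brent's method at rtol 1e-14. Percentages at exactly a
threshold never fire (strict comparison); AIC ties at 1e-9 resolution
prefer the exponential model; sales ties break lexicographically.

## Known limitations

* The engine consumes prediction tables; it cannot detect that an
  upstream tool's applicability domain or training data make a
  prediction worthless.
* Parallel-curve CA assumes constant relative potency; strongly
  non-parallel components violate the construction (the Loewe oracle
  would still apply, but curve-specific EC50s then drive the MDR).
* The MDR call is a point decision without uncertainty; near-threshold
  ratios deserve replication rather than a binary label.
* Substance-class co-formulants (no structure) are only reachable
  through the sales stream.
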