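# Methods

## Scope and model system

`ltpdigest` analyses the in vitro gastrointestinal digestion of Pru p 3, the
major peach allergen — a 9 kDa non-specific lipid transfer protein (nsLTP1)
whose 91-residue mature chain is cross-linked by four conserved disulphide
bonds. The pipeline covers five analysis stages: rule-based in silico
proteolysis, mapping of identified peptides onto isoform sequences,
disulphide-aware fragment connectivity, first-order digestion kinetics from
gel densitometry, and inhibition-ELISA IC50 analysis. A synthetic-data
generator replaces the wet-lab inputs (gels, LC-MS/MS identification tables,
ELISA plates) so the whole pipeline runs and is tested without downloads.

## Coordinate frame and fixtures

All intervals are 1-based and inclusive on the mature chain (I1…K91).
The vendored fixture carries the mature Pru p 3 sequence (UniProt accession
Q9LED1, isoform Pru p 3.0102 numbering), the three linear IgE epitopes
A11-G20, I31-T40 and G71-K80, and the disulphide topology. The topology uses
the canonical plant nsLTP1 pairing C1–C6, C2–C3, C4–C7, C5–C8, i.e. pairs
(3,50), (13,27), (28,73), (48,87); it is configurable, and
`validate_topology` checks any override against the sequence. The fixture is
gated by self-tests: epitope label letters, the eight-cysteine skeleton, and
the boundary residues of the dominant digestion products must all match the
sequence, so a corrupted fixture fails loudly.

## Cleavage rules and in silico digestion

Cleavage specificity is the classic P1/P1' rule: cleave after any residue in
the P1 set unless the next residue blocks. Defaults:

| protease     | P1 residues | blocked P1' | notes |
|--------------|-------------|-------------|-------|
| trypsin      | K, R        | P           | 7 predicted sites on the fixture |
| chymotrypsin | F, Y, W, L  | P           | broad variant incl. Leu; 6 sites incl. L10–A11 |
| pepsin       | F, L, W, Y  | P           | gastric option, off by default |

Chymotrypsin includes Leu because the extended broad-specificity rule is the
one consistent with six predicted sites on this chain, including the L10–A11
bond; pepsin is excluded from the default intestinal rule set because Pru p 3
survives the gastric phase essentially intact and the observed peptides arise
from trypsin/chymotrypsin.

`digest()` enumerates products at three specificity levels: `full`
(both termini at predicted sites or chain termini, ≤ `max_missed` internal
sites), `semi` (one enzymatic terminus) and `none` (all substrings; guarded
by a mandatory length bound on chains longer than 60 residues). Output order
is deterministic (start, then end). Peptide masses use the pyteomics residue
tables (monoisotopic and average) plus water and modification deltas
(phospho +79.9663, deamidation +0.9840, oxidation +15.9949, carbamidomethyl
+57.0215 Da monoisotopic). `digest()` is verified against an independent
brute-force enumeration oracle on random sequences.

## Disulphide-connected fragments

Cutting the backbone does not free a fragment whose cysteines are still
bridged. `build_fragment_components` splits the chain at a cut set and merges
fragments into connected components under the bridge relation (union-find).
A component's mass is the sum of member masses minus 2 hydrogen atoms per
disulphide bond internal to the component — whether the bond joins two
members or closes a loop inside one. Hydrolysis conservation (Σ fragment
masses = parent + n_cuts × H2O, to 1e-6 relative) and invariance to bridge
order are property-tested. `nonreduced_observable` implements the rule that a
peptide is detectable without reduction only when it contains no bridge-paired
cysteine; `interbridge_free_intervals` lists the maximal bridge-free regions
(for the default topology these include (51,72) — the region between Cys50
and Cys73 that dominates non-reduced digests — and the C-terminal tail
(88,91)).

## Peptide mapping, coverage, cleavage usage, epitope survival

Identification tables are filtered at score > 5 (strict, matching the
search-engine retention rule) before mapping. Mapping reports every match of
every peptide across every isoform; under opt-in I/L equivalence (MS cannot
distinguish the isobaric pair) matches that needed the equivalence are
flagged `il_ambiguous`. Exact matching is the default because isoform-unique
peptide claims require it. Unmatched peptides go to an unmapped report —
nothing is silently dropped.

Coverage is the fraction of residues touched by at least one located peptide
(denominator: the isoform's own length). Observed cleavage events are the
peptide termini excluding chain termini (an undigested protein is not
proteolytic evidence), weighted by spectral count and labelled with the
predicting protease or `non-typical`. Spectral-count abundance is normalised
per sample by total counts; raw counts are always exported alongside.

Epitope survival is a three-state decision rule: *digested* — no located
peptide spans the full epitope interval; *partially degraded* — spanned, but
an observed cut falls strictly inside the interval (a severed bond between
its first and last residue); *intact* — spanned and uncut. The rule is
validated by reproducing the three observed outcomes (I31-T40 digested,
A11-G20 and G71-K80 partially degraded) from the dominant-peptide list plus
the default cleavage predictions.

## Digestion kinetics

Band intensities are fractions of the undigested intestinal control (IU).
A two-tailed two-sample Student's t-test (equal variance; Welch by flag)
between control and final-time replicates gates the analysis at α = 0.05:
series with p ≥ α are classified resistant and reported with t½ = ∞ rather
than forced through a decay fit.

Non-resistant parent bands are fitted with I(t) = I0·exp(−K·t) by
Levenberg–Marquardt damped least squares, initialised from a log-linear
regression (deterministic; no random restarts). Because densitometry noise
scales with band intensity, the default fit is iteratively reweighted with
standard deviation proportional to the model value (three rounds; the floor
1e-6·I0 only avoids division by zero); `weighting="none"` gives the plain
unweighted fit. On noiseless data both recover (I0, K) to 1e-6 relative.
Goodness of fit is the residual standard error RSE = √(SSE/(n−2)); half-life
is t½ = ln 2 / K from the unrounded rate constant, rounded only at
presentation.

Fragment bands use the consecutive first-order model
B(t) = A·k_form/(k_deg−k_form)·(e^(−k_form·t) − e^(−k_deg·t)), with the
analytic limit A·k·t·e^(−k·t) at k_form = k_deg. When the fitted k_deg is
indistinguishable from zero (< 1e-6 min⁻¹ or within two standard errors of
zero) the model reduces to rising saturation A·(1−e^(−k_form·t)) and the
fragment is classified *rising*, reporting k_form as its rate constant;
otherwise *transient*, with peak time ln(k_form/k_deg)/(k_form−k_deg).

Estimator calibration, measured by simulation at the study's noise regime
(σ = 0.05 multiplicative, triplicates, grid 0–120 min): the median fitted K
is within 1.5% of truth for every condition, and empirical 95% CI coverage is
0.92–0.96. The *median absolute* relative error is below 5% for the four
faster conditions but 7–12% for the two slowest (K = 0.0022 and
0.0016 min⁻¹): those bands decay only 17–23% over the 120-minute experiment,
so with 5% intensity noise the Fisher information bounds any estimator's
median absolute error to roughly 8–11% — a property of the experimental
design, not of the fitter.

## Inhibition ELISA

Curves are fitted with the four-parameter logistic
y = d + (a−d)/(1 + (x/c)^b), parametrising the inflection on the log scale so
c stays positive under unconstrained Levenberg–Marquardt. Initialisation is
deterministic: a = max response, d = min response, b = 1, c = geometric mid
concentration. IC50 is reported as c (the midpoint between asymptotes, the
standard 4PL convention); estimates outside the tested concentration range
(default 1e-5–10 µg/mL, seven decades) are censored to "< min" / "> max"
bounds, and fits whose log-scale standard error on c exceeds 0.5 are flagged
approximate ("~"). Fold changes propagate censored bounds (e.g. a
censored-low reference gives a "> x" bound). The fit is scale-equivariant in
concentration and recovers c = 0.01 µg/mL with ~2% median bias under 3%-of-
amplitude additive noise.

## Synthetic-data generator

The generator's defaults are the study conditions:

* **Densitometry** — grid {0, 10, 20, 40, 60, 90, 120} min (40 and 120 min
  are the landmark endpoints of the fast and slow digests), 3 replicates,
  multiplicative Gaussian noise σ = 0.05 truncated at zero. Parent rate
  constants per condition: high-enzyme 0.0022 (pH 6.5), 0.0451 (pH 6.5 +
  4 mM bile), 0.0055 (pH 8.0), 0.1292 (pH 8.0 + 4 mM bile); low-enzyme
  0.0016 (pH 6.5 + 1 mM) and 0.0073 (pH 8.0 + 1 mM); the two low-enzyme
  bile-free conditions are fully resistant. Fragment bands rise with
  k = 0.0126 / 0.0216 min⁻¹ in the low-enzyme bile tests; in the high-enzyme
  bile tests they are transient with k_form = parent K and k_deg = k_form/4
  (the onward rate is not printed anywhere; one fixed choice).
* **Identifications** — peptides drawn without replacement from the
  semi-specific digest (≤ 2 missed cleavages, 6–30 residues, 500–5000 Da;
  pool ≈ 325 peptides, ≈ 101 untethered), with dominance weight 400 on the
  preferred products so they are near-certain picks; reduced samples draw
  97–114 peptides, non-reduced 21–23 from the untethered pool only.
  Spectral counts are log-normal (µ = 1.2, σ = 1.0 on the log scale) with a
  6× boost for dominant peptides; serines 55/57/82 are phosphorylated with
  probability 0.3 when covered; carbamidomethyl-C is fixed on reduced
  samples; 15% of scores fall at or below the 5.0 retention threshold to
  exercise the filter.
* **ELISA** — 4PL responses on the seven-decade grid with additive noise
  σ = 0.03·a; six patients with intact-IC50 0.005–0.17 µg/mL, digest IC50s
  similar, and bile-digest IC50s 80–6000× higher, two of them beyond the
  grid to exercise censoring.

Each table draws from its own stream (`default_rng([seed, stream])`), so a
fixed seed reproduces outputs byte-identically and regenerating one table
never perturbs another.

What the generator does **not** emulate: search-engine score distributions
and FDR structure, retention times and raw spectra, inter-replicate
correlation in densitometry, isoform mixtures (it draws from the single
mature chain), plate/edge effects in ELISA, and genuinely non-typical
cleavage chemistry (non-typical sites enter only through semi-specific
termini). Passing tests therefore demonstrate the correctness and
calibration of the analysis under the declared statistical model, not
robustness to every artefact of real gels, spectra or sera.

## Numerical choices and degenerate inputs

Convergence uses scipy's LM with tight tolerances (xtol = ftol = 1e-12,
bounded iterations); all initialisations are deterministic. A constant decay
series degenerates to K = 0 (flagged, t½ = ∞) rather than erroring; an
all-zero series errors. The t-test returns p = 1 when both groups are
identical with zero variance. Non-specific digestion of chains longer than
60 residues without a length bound raises (combinatorial guard). Problem
sizes in the test suite and reproduction script (200 simulated series per
condition, 100 random oracle sequences) keep the default run under a few
minutes on one CPU while leaving Monte-Carlo margins well clear of the
asserted tolerances.

## Known limitations

* The three-state epitope rule treats any internal cut as degradation; it
  does not weight by abundance of the cut species.
* Kinetic fits treat replicates as independent observations pooled into one
  series; no mixed-effects structure.
* Censored IC50 bounds are propagated arithmetically, not by likelihood.
* The disulphide topology is an assumption (configurable), not an
  experimentally determined connectivity.
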