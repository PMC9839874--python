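# Methods

`aopfinger` turns the adverse outcome pathway (AOP) framework into a
quantitative analysis layer for toxicogenomics. An AOP is a causally ordered
chain of key events (KEs) from a molecular initiating event (MIE) to an
adverse outcome (AO); once every KE is linked to a gene set, transcriptomic
signatures can be read against whole pathways instead of individual genes.
This note documents the models and procedures, the parameters that matter,
the numerical choices, and what the synthetic fixtures do and do not show.

## Text matching of KEs to gene-set terms

KE and term descriptions are reduced to token sets in a fixed order:
lower-casing, punctuation removal, multi-word concept collapse (e.g.
"positive regulation" → "upregulated"), whitespace tokenization, stop-word
removal, and root mapping (plural and inflection stripping with a
doubling-consonant repair, plus an exception dictionary that also unifies
symbol styles such as "pparα"/"pparalpha" → "ppar-alpha"). Two deliberate
choices:

* **Intra-word hyphens survive punctuation removal.** The dictionary's own
  normalized symbols contain hyphens; removing them would make preprocessing
  non-idempotent.
* **Root mapping iterates to a fixed point** and every mapping target is
  registered as its own root, so `preprocess(preprocess(x)) == preprocess(x)`
  holds for arbitrary input. The rule-based stemmer is conservative and
  auditable rather than linguistically complete; exceptions belong in the
  editable concept dictionary (`data/concepts.tsv`). The stop-word list is
  shipped frozen (`data/stopwords.txt`) so results do not depend on any
  external resource version.

Tokens are weighted by inverse document frequency, idf(t) = ln(N/df(t)),
computed over the combined corpus of KE and term descriptions (N documents).
Candidate terms are scored with the IDF-weighted Jaccard index

    JIW(A, B) = Σ_{t ∈ A∩B} idf(t) / Σ_{t ∈ A∪B} idf(t)

and the top five candidates per KE are emitted for human curation; ties break
by term id for determinism. Matching operates on descriptions, falling back
to the title/name when a record has no description. Accepted matches are
merged into one gene set per KE; a term with no human genes contributes the
human orthologs of its mouse/rat genes (explicit two-column mapping table),
and a KE whose accepted terms all resolve to nothing is dropped and logged.
Curation itself stays human: the package never auto-accepts a candidate.

## Enrichment and the AOP fingerprint

Over-representation of a query gene set in a target set uses the one-sided
hypergeometric tail, p = P(X ≥ overlap) with population = the gene universe,
adjusted by Benjamini–Hochberg across all sets tested in one call. The
default universe is the union of all genes across KE gene sets — the scope of
the annotation — and is overridable. FDR is corrected per pass (all AOPs in
one family, all KE groups in the other), not pooled across the two levels.

A chemical screen tests CTD-style chemical gene profiles (only chemicals
with 50–1000 genes) against per-AOP gene sets (union over the AOP's KEs);
AOPs with FDR < 0.01 are ranked by FDR, then raw p, then id, and the top
five significant AOPs are checked for relevant labels.

An exposure's mechanism of action (MOA) is the pooled union of DEGs over all
comparisons, with strict thresholds |FC| > 1.5 (linear scale) and BH-adjusted
p < 0.05. The AOP fingerprint runs two enrichment passes — AOP-level on the
union sets and KE-level on identical-gene-set groups — and an AOP passes when

    FDR(AOP) < 0.05  AND  (coverage ≥ 1/3  OR  (n_KE < 6 AND n_enriched ≥ 2))

where coverage counts original KEs inheriting their group's verdict, and the
AOP length for the minimum-2 rule is the original KE count. Both counts stay
commensurable with per-KE reporting of long AOPs (e.g. seven of eight KEs
enriched). The pass rule is monotone: enriching one more KE group can never
turn a pass into a fail.

## KE grouping and network merging

KEs are grouped when their gene sets are exactly equal (Jaccard index 1).
Grouping is implemented by hashing frozen sets; a complete-linkage
hierarchical clustering on 1 − JI cut at height 0 is provided as an
equivalent alternative path (set equality is transitive, so the two
partitions provably coincide, and tests compare them on every fixture).
Group ids are the lexicographically smallest member KE id for stable output.

The KE network has one node per distinct KE across the selected AOPs and
directed edges from KE relationships; node attributes carry the member AOPs
and role. Merging collapses nodes by group, unions attributes, drops
self-loops and collapses parallel edges (keeping the list of supporting
AOPs). The containment report lists every AOP whose merged node and edge
sets are subsets of the union over the other AOPs — the phenomenon where one
pathway turns out to be fully redundant once duplicate events are merged.
Graphs are exported as GraphML with list attributes serialized as
";"-joined strings.

## Biomarker prioritization

The robust gene–gene network keeps an edge when its source count reaches the
local mean source count of at least one endpoint (m(v) = mean n_sources over
v's incident edges; keep iff n_sources ≥ m(u) or ≥ m(v)). This local rule
retains edges of sparsely studied genes where a global cutoff would not, and
it can never isolate a node (a node's best-supported edge always satisfies
max ≥ mean). The directed TF→target network is not source-filtered (too few
sources to discriminate), via a bypass flag.

Per node, four centralities are computed with NetworkX: degree (total degree
on directed graphs), betweenness, closeness, and eigenvector centrality
(power iteration, tolerance 1e-10, max 1000 iterations, uniform start;
directed graphs fall back to the undirected view if iteration fails to
converge, logged). Closeness uses the Wasserman–Faust convention — computed
within each node's reachable set and scaled by (reachable−1)/(N−1) — so
values are comparable across components.

Rank aggregation uses the Borda method with the arithmetic mean of ranks
(median/geometric variants exist in the literature; mean is the package
default). Genes missing from a list receive that list's worst rank + 1.
Within each target KE, the four centrality lists are combined per network,
then across networks (a pooled-all-lists mode is available via `combine=`),
then combined with the KE-level and AOP-level specificity ranks; a final
Borda across the target KEs yields the global rank. Specificity is the
occurrence ratio n_target/n_other over distinct KE (or AOP) gene sets, with
n_other = 0 mapping to +∞ (serialized as "inf") and ranked first.
Candidate selection is tiered by experimental evidence — (1) deregulated in
vivo and in vitro, dose-dependency emphasized within the tier; (2)
deregulated in vitro; (3) dose-dependent without differential expression —
restricted to the top 10% of the global rank, plus a trailing coverage tier
that admits the best-ranked gene of any target KE left uncovered.

## Benchmark-dose modeling

Each feature is fitted by bounded multi-start least squares (5 deterministic
starts per model, trust-region reflective) over a model family:
transcriptomics = {linear, 2nd-order polynomial, hill, power, exponential};
qPCR additionally {log-logistic, weibull, michaelis_menten}. The
parameterizations (d = dose):

| model            | f(d)                                  | constraints        |
|------------------|---------------------------------------|--------------------|
| linear           | a + b·d                               | —                  |
| poly2            | a + b·d + c·d²                        | —                  |
| power            | a + b·d^g                             | g ∈ [0.5, 8]       |
| exponential      | a + b·(e^{c·d} − 1)                   | \|c\|·d_max ≤ 5    |
| hill             | a + (b−a)·dⁿ/(kⁿ + dⁿ)                | n ∈ [0.5, 8]       |
| michaelis_menten | hill with n = 1                       | —                  |
| log_logistic     | a + (b−a)/(1 + (d/e)^{−β})            | β ∈ [0.2, 20]      |
| weibull          | a + (b−a)·(1 − e^{−(d/k)^g})          | g ∈ [0.2, 8]       |

Dose-scale parameters and their bounds are expressed through the maximum
tested dose, so rescaling doses by c rescales BMD/BMDL/BMDU by c (tested as
a property). The exponential rate bound keeps the curvature identifiable
inside the tested range; an unbounded rate lets the optimizer wander into
flat overflow regions.

Model selection minimizes AIC = n·ln(RSS/n) + 2(p+1), counting the residual
variance as a parameter; the additive constant is omitted consistently, so
within-feature comparisons are exact (RSS is floored at 1e-12 to keep AIC
finite on interpolating fits). Lack of fit is the F-test of the model
against the saturated per-dose-means model; features with p < 0.10 are
removed. When replication is insufficient the statistic is undefined (NaN)
and the lack-of-fit filter does not fire.

The benchmark response is BMR = 1.349·σ, with σ = sqrt(RSS/(n−p)) from the
selected model (constant-variance assumption; a pooled per-dose σ is a noted
alternative). The factor 1.349 standard deviations corresponds to roughly a
10% change relative to controls. The BMD is the smallest dose where
|f(d) − f(0)| = BMR, searched up to 10× the highest tested dose (grid scan +
Brent refinement); no crossing means no BMD. BMDL/BMDU are 95% two-sided
profile-likelihood bounds: the profile RSS(δ) from equality-constrained
SLSQP refits is compared against RSŜ·exp(χ²₀.₉₅/n), with 12 bisection steps
per side over (BMD·10⁻³, min(10·d_max, 50·BMD)). Two consequences are
intentional:

* If the profile never rejects inside the window, the bound is **not
  estimable** and reported absent. Noise-chasing fits on flat features have
  unconstrained BMD profiles, so they fail any rule requiring BMD, BMDL and
  BMDU to exist — the behavior that makes the dose-dependence verdict
  specific.
* Bound resolution is limited by the bisection step (~0.1–1% of BMD); very
  tight profiles can return BMDL or BMDU numerically equal to BMD.

A parametric-bootstrap alternative (percentile bounds over refits of the
selected model) is available via `BmdConfig(bounds_method="bootstrap")`.
Features pass the dose-dependence filter when lack-of-fit p ≥ 0.10, BMD and
BMDU do not exceed the highest tested dose, and BMD/BMDL ≤ 20, BMDU/BMD ≤ 20,
BMDU/BMDL ≤ 40.

## qPCR statistics

Relative expression uses the comparative Ct method: dCt = Ct(gene) −
Ct(reference, default ACTB) per sample; ddCt = dCt − mean control-group dCt
per gene; FC = 2^(−ddCt). The computation is invariant to per-sample
additive Ct shifts. Samples lacking a reference Ct are dropped with a
warning.

Outlier filtering per gene × concentration retains values inside [Q1, Q3]
(type-7 linear-interpolation quartiles). As stated this removes roughly half
of each group — it is implemented exactly so, with a conventional 1.5×IQR
fence available as `mode="iqr-fence"`; groups under 3 values are left
unfiltered. Note that trimming deflates the within-group variance, which
makes the downstream lack-of-fit test stricter than its nominal level — a
property of the procedure, visible in the fixtures as occasional planted
genes failing the dose-dependence verdict.

Dose effects are tested per gene with one-way ANOVA across concentrations
(significance at p < 0.05, the package-wide convention) and Tukey HSD
post-hoc comparisons; genes without ≥2 groups of ≥2 values are untestable.
Dose-dependence delegates to the benchmark-dose module with the extended
qPCR family; a gene is relevant when lack-of-fit p > 0.10 and BMD, BMDL and
BMDU were all estimable. The summary verdict table nests its columns the way
a validation experiment reads: only detected genes (any finite Ct) can be
deregulated, and dose-dependence is evaluated among the deregulated genes.

## Synthetic fixtures

Every input shape is generated deterministically from a `FixtureConfig`
(one global seed; per-generator streams derived through fixed offsets, so
identical config + seed reproduce identical outputs and stages can be
regenerated independently). Defaults are the package's study conditions:

* **Corpus**: 150 terms, 50 KEs, 8-token descriptions over a 600-token
  vocabulary; each KE description paraphrases its true term at 20% token
  swap noise. Emits a KE→term truth table.
* **AOP scaffold**: 12 AOPs of 4–8 KEs as linear chains, 30–150 genes per KE
  from a 2000-gene pool, 20% duplicate-gene-set rate, plus one planted AOP
  duplicating a sub-path of the first AOP (fresh KE ids, identical sets) so
  that merging reveals it as fully contained. Emits the true partition and
  containment.
* **Chemicals**: 10 profiles of 80–400 genes sampling 60% from one labeled
  target AOP.
* **MOA DEG tables**: 3 comparisons; planted genes from target AOPs get
  |log2FC| ∈ [1, 3] and adjusted p < 0.01 (active in ~70% of comparisons);
  background genes get N(0, 0.6) log-fold-changes and uniform p, so a
  zero-signal run yields a non-empty random MOA for null calibration.
* **Sourced edges**: a 12-gene core clique of support-8 edges, each of 24
  periphery genes attached by one support-5 and one support-1 edge; the
  surviving subgraph under the local-mean rule is known analytically.
* **Dose-response expression**: linear, hill and flat genes on a geometric
  dose grid (0–8, 6 doses × 4 replicates) with known true BMDs from the
  generating σ (default 0.2; tests use 0.05, i.e. ≤5% of the response range).
* **qPCR Ct tables**: the bleomycin exposure grid (0, 2.5, 5, 10,
  100 µg mL⁻¹), 5 samples per concentration, a flat ACTB reference at Ct 20,
  25 genes of which 5 are planted with saturating upregulation (half-max
  near the mid doses, ~2.4 log2 units at top dose) — the typical shape of an
  induced transcript.

What the fixtures do **not** emulate: real AOP-Wiki prose style beyond
token-level paraphrase, transcriptome covariance between genes, annotation
bias, multi-tissue structure, or qPCR efficiency differences. Passing the
planted-recovery tests therefore shows the pipeline's decision rules and
estimators are implemented correctly and are well calibrated under clean
planted signal — not that real exposures will reach the same recovery.

## Known limitations

* Exact-equality KE grouping is deliberate (one enrichment test per distinct
  set); approximate grouping at JI < 1 is out of scope.
* The profile-likelihood bounds assume the χ²(1) calibration of the
  likelihood-ratio statistic; at very small n it is approximate.
* The lack-of-fit test needs replication; single-replicate designs pass
  through unfiltered (statistic undefined).
* Rank aggregation order (per-network-then-across vs pooled) changes results
  slightly; both are exposed, per-network-then-across is the default.
* qPCR quantification is the pure ddCt model; efficiency-corrected (Pfaffl)
  quantification and amplification-curve processing are out of scope.
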