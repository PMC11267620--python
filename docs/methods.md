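# Methods

## Study design being modelled

The pipeline analyzes a two-group neuronal cell experiment: SH-SY5Y cells
stably expressing huntingtin with a wild-type (Q23) or expanded (Q74)
polyglutamine tract, four aliquots per line, profiled for ~2,083 mature
miRNAs by a counting assay. Downstream, differentially expressed miRNAs
are matched to candidate target mRNAs by a full-length hybridization-energy
scan, and a panel of candidate genes is validated by triplicate qPCR
against an 18S reference. No per-sample raw data are publicly deposited for
this design, so the package treats the synthetic-data generators as the
canonical input source and the published summary arithmetic (group means,
fold changes, mean expressions) as worked examples.

## Differential expression

* **Normalization** — counts per million: each sample is scaled so its
  column sums to 10⁶. CPM exactly absorbs per-sample scale factors
  (pipeline equivariance is property-tested) but, like any total-count
  normalization, it is subject to composition effects when many features
  truly change; see *Limitations*.
* **Transform and test** — log2(CPM + pseudocount), pseudocount default
  1 CPM; per-miRNA two-sample Student's t-test (equal variances by default,
  Welch available) on the log scale, where count noise is closest to
  homoscedastic. Rows with zero variance in both groups and equal means get
  p = 1. The test is run on log2 CPM rather than raw CPM because the
  fold-change scale is multiplicative; this is a documented choice, not a
  mathematical necessity.
* **Multiplicity** — Benjamini–Hochberg by default (`statsmodels`
  `multipletests`; the method name is configurable). "Differentially
  expressed" means adjusted p < α (default 0.05), the conservative reading
  of a printed adjusted-p column.
* **Fold change convention** — signed: disease/control when disease ≥
  control, else −(control/disease), so |FC| ≥ 1 always and down-regulation
  is immediately visible as a negative number. Mean expression is
  log2((mean_control + mean_disease)/2), both in CPM. Both are computed
  from unrounded group means; presentation rounding (2 dp) happens only at
  TSV-writing time. If a group mean is exactly zero (possible for very low
  negative-binomial baselines), a detection floor of 0.5 CPM is substituted
  before the ratio/log so the records stay defined; this floor never
  engages on the worked-example arithmetic.
* **Top-k selection** — k_up best-adjusted-p upregulated rows followed by
  k_down downregulated (defaults 8 and 10, i.e. a "top 18"); ties break by
  |FC| descending, then id.

## Hybridization-energy target scan

* **Model** — an ungapped antiparallel duplex over the whole miRNA: miRNA
  position i (5'→3') pairs with window position L−i+1. Admissible pairs
  carry fixed hydrogen-bond counts — A–U 2, G–C 3, G–U 2, A–C 1 — times a
  single per-bond free energy ε_H, default −2.1 kJ/mol; any other base
  combination contributes 0. ΔGm is the energy against the exact reverse
  complement, a composition-only quantity; site quality is the percentage
  ΔG/ΔGm, and sites at 80–100% are retained by default.
* **Why these numbers** — the per-pair energies of the original
  binding-site predictor this emulates are not published alongside the pair
  inventory and inter-nucleotide distances (A–C 1.04, G–C/A–U 1.03, G–U
  1.02 nm; stored as metadata, no energetic role). The bond counts are the
  physical hydrogen-bond numbers of each pair; ε_H = −2.1 kJ/mol puts
  ΔGm per nucleotide in [−6.3, −4.2] kJ/mol across GC content, which
  brackets the per-nucleotide magnitudes implied by published site tables
  (e.g. two sites of one 16-nt miRNA at −72/83% and −76/88% both imply
  ΔGm ≈ −86.5 kJ/mol, i.e. −5.4 kJ/mol/nt). Exact reproduction of
  published per-site ΔG values is explicitly not promised — reference mRNA
  versions are uncited, so printed coordinates and energies are calibration
  references only.
* **Scan mechanics** — every window start is scored (vectorized bond-table
  lookups); retained windows (ratio ≥ threshold) are reduced to local
  maxima: a window survives iff it strictly beats every overlapping
  retained window on ratio, ties going to the smaller start. A brute-force
  per-window enumerator with the same filtering contract, written
  independently, serves as the test oracle. Site starts are 1-based on the
  mRNA sense strand; a site is localized to the region (5'UTR/CDS/3'UTR)
  containing its start; DNA input is mapped T→U on load.
* **A subtlety of the default bond table** — G–U wobbles score 2 bonds,
  the same as A–U, so a window that replaces an A (opposite a miRNA U)
  with G still reaches ratio 100 without being the exact reverse
  complement. "Ratio 100 iff exact reverse complement" therefore holds only
  under a *strict* model in which every substitution strictly loses bonds
  (e.g. wobble bonds lowered); the test suite asserts the forward
  implication under defaults and the full equivalence under a strict model.
* **No folding** — this is a bond-counting model, not nearest-neighbor
  thermodynamics: no stacking, bulges, loops or gap penalties. It is the
  intended reimplementation of the described algorithm, not a replacement
  for RNAduplex-style folding.

## qPCR relative quantification

The plain Livak 2^−ΔΔCt formulation: per-replicate ΔCt = Ct(target) −
Ct(reference) paired by replicate index within group; ΔΔCt is the
difference of group means; FC = 2^−ΔΔCt with amplification efficiency
fixed at 2 (no standard-curve correction). The t-test runs on per-replicate
ΔCt values — Ct space is where Gaussian noise is plausible — never on fold
changes. Adding a constant to every Ct of one replicate cancels in ΔCt
(reference invariance); swapping group labels maps FC to 1/FC with the same
p (both property-tested). Stars follow the usual convention (* p<0.05,
** p<0.01).

## Synthetic data: what it emulates and what it does not

* **Counts** — per-miRNA baseline abundances drawn log-uniformly
  (1–10,000), planted up/down fractions defaulting to the study's design
  (126 up, 228 down of 2,083) with fold changes log-uniform in 2–18,
  negative-binomial counts with var = μ + φμ² (φ default 0.1; φ = 0 gives
  Poisson), and library sizes drawn uniformly from 0.5–2 million so the CPM
  step has real work to do. NB is the standard count model for sequencing
  assays; the true replicate dispersion of the emulated assay is unknowable
  from published summaries, so φ is a parameter, not a claim.
* **Transcripts** — uniform-random RNA split contiguously into
  5'UTR/CDS/3'UTR (default 10/60/30%). Planted sites start as exact reverse
  complements and are degraded by zero-bond substitutions (writing the
  miRNA's own base at a paired window position, which no pair table
  entry matches) chosen in seeded random order until the realized ratio
  enters the requested band; infeasible bands raise a generation error.
* **qPCR** — reference Ct fixed at 10 (abundant housekeeping RNA), target
  baselines uniform in 20–30 cycles, disease Ct shifted by −log2(planted
  FC), Gaussian per-well noise.
* **What passing tests show** — that the implementation recovers exactly
  what was planted under its own generative assumptions. Real data differ:
  miRNA abundances are heavy-tailed rather than log-uniform, real
  transcripts have composition and repeat structure that changes the
  background ratio distribution, dispersions vary per miRNA, and qPCR noise
  is not i.i.d. Gaussian. Passing here validates the arithmetic and the
  contracts, not biological discovery performance.

## Numerical and procedural choices

* Determinism: every generator takes a seed and uses `numpy.random.
  default_rng`; identical config + seed reproduces byte-identical TSVs
  (asserted end-to-end).
* Ratio comparisons use an absolute tolerance of 1e-9 percentage points;
  retained-band membership and local-max ties use the same epsilon.
* A scan threshold above 100% retains nothing (allowed, returns empty); a
  transcript shorter than the miRNA warns and returns no sites in
  single-scan mode, and is skipped silently in bulk mode.
* The DE stage's composition caveat is real: planting many one-directional
  effects shifts library totals, so null miRNAs drift slightly between
  groups under plain CPM and the realized false-discovery proportion
  exceeds the BH nominal level. The pipeline keeps plain CPM because that
  is the procedure being reimplemented; calibration is therefore asserted
  on null-only data, and direction fidelity on the planted miRNAs.
* Published summary tables round group means to integers; recomputed fold
  changes/mean expressions are compared at ±0.01 to absorb that input
  rounding. Rows whose printed fold change cannot be produced from their
  printed means under any rounding (printed from unrounded internal data)
  are excluded from the worked examples, as are printed adjusted-p values
  above 1 (typographical).

## Limitations

* The energy parameterization is calibrated to magnitude bands, not to the
  original predictor's unpublished constants; per-site ΔG values are
  comparable in scale, not digit-for-digit.
* No isomiR/hairpin structure, no probe chemistry, no conservation or seed
  heuristics, no genome-scale scans: scope ends at the described
  algorithmic chain at desk scale.
* Disease annotations are consumed as a provided table; no resource mining
  or network access anywhere in the package.
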