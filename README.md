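# mirhd

A tested re-implementation of a miRNA biomarker-discovery pipeline for a
polyglutamine (polyQ) Huntington's-disease cell model: SH-SY5Y neuronal
cells stably expressing huntingtin with a normal (Q23) or expanded (Q74)
glutamine tract. It is aimed at computational biologists who want the whole
analysis chain — count normalization, differential expression, binding-site
prediction, qPCR validation and the integrated miRNA–target report — as
plain, testable Python, exercisable end to end on synthetic data with
planted ground truth.

## What it computes

**Differential expression.** Raw miRNA counts (2,083 miRNAs × 4+4
replicates in the emulated design) are scaled to counts per million
(CPM = count / library size × 10⁶) and log2-transformed. Each miRNA gets a
two-sample Student's t-test on log2 CPM, Benjamini–Hochberg adjustment, and
a signed fold change:

    FC = mean_disease / mean_control          if disease ≥ control
       = −(mean_control / mean_disease)       otherwise

together with the mean expression log2((mean_control + mean_disease)/2).

**Target prediction.** Each miRNA is slid along each mRNA (5'UTR + CDS +
3'UTR) and scored over its *entire* length as an ungapped antiparallel
duplex. Position *i* of the miRNA (5'→3') pairs with window position
L−i+1; each admissible pair contributes its hydrogen bonds (A–U 2, G–C 3,
and the non-canonical G–U 2, A–C 1) times a per-bond energy of −2.1 kJ/mol:

    ΔG = Σᵢ n_H(pairᵢ) · ε_H,     ΔGm = ΔG against the exact reverse complement

Sites with ΔG/ΔGm between 80 and 100% are retained, reduced to local maxima
of the ratio among overlapping windows, localized to 5'UTR/CDS/3'UTR, and
rendered as two-line pairing schemes ('|' canonical, ':' wobble).

**qPCR validation.** Triplicate Ct values are analyzed by the 2^−ΔΔCt
method against an 18S reference: ΔCt = Ct(target) − Ct(18S) per replicate,
ΔΔCt = mean ΔCt(disease) − mean ΔCt(control), FC = 2^−ΔΔCt, with a t-test on
the per-replicate ΔCt values.

**Integration.** DE miRNAs are joined to their predicted sites, qPCR calls
and a user-supplied gene→disease table; multi-site pairs collapse to the
`1758÷2319 (2)` start dialect.

The `mirhd.simulate` module generates every input with planted truth
(planted DE directions and fold changes, planted binding sites of known
ΔG/ΔGm, planted qPCR fold changes), so each stage is checked against what
was planted.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 2024) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_target_scan.py
python analysis/04_qpcr_validation.py
python analysis/05_integrated_report.py
```

which prints, among other lines:

```
counts: 2083 miRNAs × 8 samples, 354 planted DE (126 up / 228 down)
DE: 265 significant (91 up / 174 down) of 2083 miRNAs
truth: 240/354 planted miRNAs detected, 0 direction flips
scan: 23 sites retained at ratio ≥ 80% ({'CDS': 15, "3'UTR": 7, "5'UTR": 1})
planted-site recovery: 20/20 at exact start
qPCR panel: 1 up, 4 down, 13 ns
```

Reading: of 354 planted DE miRNAs, 240 are recovered at BH-adjusted
p < 0.05 with four replicates per group and not one flips direction; every
planted binding site is rediscovered at its exact start; the qPCR stage
recovers the strongly planted genes, while weakly shifted ones (FC ≈ 1.3–1.4
at triplicate noise) stay non-significant — the honest power of n = 3.

The same pipeline is available as a CLI (`mirhd simulate|de|scan|qpcr|
report|run`); `mirhd run --outdir <dir>` executes all five stages from a
YAML config and writes a manifest.

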