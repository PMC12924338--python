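# Methods

## The inference problem

Transcriptome-derived proteomes of non-model eukaryotes carry no
experimental localization data. Compartment assignment must come from
N-terminal targeting-peptide predictors benchmarked on a related model
organism, under the assumption that the features defining chloroplast
transit peptides (cTP) and mitochondrial transit peptides (mTP) are shared
between the model and the target species. The pipeline therefore has three
coupled parts: a benchmark that selects trustworthy predictors, a
deliberately conservative consensus that converts their calls into
assignments, and an independent feature-level validation that checks whether
the assigned cohorts actually look like cTP- and mTP-bearing proteins.

## Consensus model

Let T be the set of selected tools (the top k = 3 of the benchmark ranking)
and c_t(p) tool t's canonical call for protein p. The assignment rule, in
order of precedence:

1. p has an incomplete N-terminus → `unassigned` (rule `truncated`). A
   truncated transcript has lost exactly the region all predictors read.
2. all t ∈ T agree on a class in {plastid, mitochondrion, secretory} → that
   class (rule `unanimity`).
3. the designated multi-class tool calls membrane or peroxisome and every
   other tool calls `other` → the multi-class call (rule `multiclass_only`).
   Only one of the benchmarked predictor families distinguishes these two
   classes at all, so unanimity is structurally impossible for them.
4. otherwise `unassigned` (rule `none`).

Two exact consequences are asserted as tests rather than estimated: the set
of proteins assigned to class c is a subset of every tool's c-called set
(hence consensus recall ≤ min tool recall per class), and no protein
receives membrane/peroxisome unless the multi-class tool called it. The
precision gain is statistical, not exact, and is checked by simulation:
with three conditionally independent tools at 0.85 per-class accuracy and
errors spread evenly, a unanimous wrong call requires three identical
independent errors (probability ≈ (0.05)³ per wrong class), so consensus
precision approaches 1 while single-tool precision stays near 0.86.
Secretory is treated like the two organellar classes because extracellular
predictions flow through the same unanimity logic. Votes are categorical;
no score thresholds or weighting are applied.

## Benchmark

Per tool, gold labels × emitted calls are tabulated into a confusion matrix
with an explicit `no-call` column; a labeled protein the tool did not score
counts as a false negative for its gold class (an unscored organellar
protein is a missed one). One-vs-rest metrics per class report undefined
ratios as missing, never as zero. Tools are ranked by a chosen metric —
default MCC, being robust to the heavy class imbalance of localization
gold sets — averaged without weights over the plastid and mitochondrion
classes; ties break lexicographically by tool id. An optional per-class
precision floor can exclude a tool with excessive false positives for one
organelle before ranking (off by default).

## Transit-peptide features

Positions are 1-based over the full sequence, the initiator Met being
position 1. Charge uses K/R = +1, D/E = −1, H = 0 (assumed physiological
pH; configurable), X = 0. The positional charge profile averages residue
charge at each position over all cohort sequences long enough to reach it.
GLK sites are scanned with a configurable grammar; the default calls a site
any 4-residue subwindow containing ≥ 3 distinct letters of {F, G, L, K},
with the subwindow start inside the scan window (plastid default 1–40,
mitochondrial 1–20, matching the ~40/~20-residue windows in which these
Toc-interaction motifs concentrate). Published definitions of the motif
vary, which is why every grammar component is a parameter rather than a
constant. Position-specific residue enrichment is
log₂(((count + ψ)/(n + 20ψ)) / background) with pseudocount ψ = 0.5; the
full 20-residue table is reported so any sentinel-residue set can be read
off. Sequences flagged N-terminally partial are excluded from all feature
cohorts by default.

## Pathway matrices and filters

Evidence rows (one per homolog/paralog) are scored independently:
no homolog → `absent`; prokaryote best hit → `contaminant_only` (a
metatranscriptome contaminant contributes no localization — in a mixed
cell only the eukaryotic paralogs carry evidence); truncated consensus →
`present_truncated`; unassigned consensus → `present_unassigned`;
consensus matching the expected compartment (or any assignment when no
expectation is declared) → `present_consistent`. A prediction that
contradicts a declared expectation is reported with its localization but
scored `present_unassigned`, since the status vocabulary deliberately has
no "present-but-contradicting" value. A cell with several paralogs takes
the strongest status and reports the set of predicted localizations; no
single-winner rule is imposed on conflicting paralogs. Pathway
completeness is the fraction of member enzymes in any `present_*` status;
complete means all of them — one missing enzyme (the carbamate-kinase
situation) voids the pathway.

Community filtering retains a lineage for a culture when its relative
abundance is ≥ 1% there; a value exactly at the threshold is retained,
because the discard rule targets lineages *below* 1%. Shared-lineage
comparison intersects the post-filter sets, optionally restricted by an
oxygen-preference tag.

## Spectral statistic

The unsaturation ratio is I(1656)/I(1440) — C=C stretch over CH₂
deformation — computed on a baseline-corrected spectrum. Baseline
correction subtracts the straight line through the (mean wavenumber, mean
intensity) points of two flat anchor windows flanking both bands (defaults
1300–1350 and 1750–1800 cm⁻¹), which maps any linear baseline to zero
exactly. Band intensity defaults to the local maximum within ±10 cm⁻¹ of
the band center; integrated area over the same window is available as an
option, since published band-ratio protocols use either. The ratio is
invariant to global intensity scaling and, after correction, to linear
baselines; both invariances are asserted as tests.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analyses assume, with
one global seed and per-generator substreams spawned deterministically from
it (`numpy` `SeedSequence.spawn`).

**Proteomes.** Plastid proteins are M + cTP (40–70 residues) + mature
domain; the first 9 residues after the Met have K/R sampling probability
divided by 3 and the middle third of the cTP has it multiplied by 3, so in
full-sequence coordinates positions 1–10 are relatively uncharged and the
charge maximum falls in the middle third. Mitochondrial proteins are
M + mTP (20–60 residues) + mature, K/R boosted ×3 in the first 9 residues
after the Met. One literal FGLK 4-mer is planted with probability 0.8
(plastid, within the first 40 positions) or 0.6 (mitochondrial, first 20);
spontaneous background sites are not suppressed. Secretory proteins get a
minimal hydrophobic leader (15–25 of A/L/V/F) — the class exists only as a
distractor. "Other" proteins are a mature domain alone; like every
generated sequence it starts with the initiator Met, since a complete
transcript's protein does and a non-Met start would spuriously flag the
whole class as truncated. Residues are otherwise drawn from a background
distribution whose default downweights the motif alphabet (F/G/L/K at 0.02
each, the other 16 residues uniform) so that spontaneous GLK-like 4-mers
stay rare and planted-site probabilities remain interpretable as
prevalences; with a composition-realistic background (G+L ≈ 17%),
spontaneous sites would dominate the motif signal. The generator makes no
attempt to mimic real amino-acid composition, hydrophobicity structure, or
assembly artifacts beyond the is_partial flag — so passing feature-recovery
tests shows the analyzers measure what the generator planted, not that real
presequences will be this clean.

**Predictor calls.** Each simulated tool draws its emitted class from a
row-stochastic confusion matrix conditioned on the gold class,
independently across proteins and tools. Real predictor errors are
correlated (hard proteins are hard for everyone), so the simulated
precision gain of consensus voting is an upper bound on what correlated
tools would deliver.

**Community tables.** Two cultures, 18 lineages each by default: 7 shared
(tagged anaerobic/microaerophilic), 6 culture-specific (aerobic), 5 noise
lineages forced below the 1% threshold (uniform 0.1–0.8%). Retained
lineages get a 2% floor plus a Dirichlet-distributed share of the
remaining mass, so the retained/noise split is exact by construction, not
probabilistic. Defaults mirror a two-culture setting with 13 genuine
lineages each and 7 shared.

**Spectra.** Intensity = linear baseline + Gaussian at 1440 cm⁻¹ (height
1, width 14) + Gaussian at 1656 cm⁻¹ (height = true_ratio, width 12) +
iid Gaussian noise, on a 1300–1800 cm⁻¹ axis at 1 cm⁻¹ steps. Default
true_ratio 1.07 represents a monounsaturated triacylglycerol profile. Real
Raman spectra have non-linear fluorescence backgrounds and multiplicative
noise; the linear-baseline model is the simplest defensible default and
the band-ratio code accepts any externally corrected spectrum.

## Numerical and edge-case choices

- FASTA partiality: is_partial = first residue ≠ M, or a "partial" token
  in the description; illegal residues error with record id and position.
- Undefined benchmark ratios (empty denominators) are NaN; MCC with a zero
  denominator is NaN.
- Motif scan windows extending past the sequence end are clipped with a
  warning rather than erroring.
- Enrichment errors on any zero background frequency (the log-odds would
  be infinite), advising a pseudocount on the background itself.
- Community column sums are normalized to 1 exactly; the filter boundary
  keeps values equal to the threshold.
- Cohort ratio dispersion uses the n−1 sample standard deviation; a
  single-spectrum cohort reports NaN dispersion.
- All pipeline outputs are sorted on stable keys, so results are
  independent of input row order and byte-identical across reruns with
  one seed.

## Problem sizes

The simulation-backed checks use 5000-protein cohorts for consensus
precision and random-guess MCC, 2000 for confusion recovery, 500 per class
for the generator↔feature loop, 20 spectra for ratio recovery, and ≥ 100
randomized fixtures per brute-force oracle comparison. These sizes put the
binomial sampling error of each estimate well inside the asserted
tolerances (e.g. ±0.03 on a 0.85-accuracy estimate at n = 2000 is ≈ 3.8
standard errors).

## Known limitations

- Conditional independence of simulated tool errors overstates consensus
  gains relative to correlated real predictors (see above).
- The GLK-site grammar is a configurable reading of the motif concept, not
  a reimplementation of any specific published site definition.
- No dual-targeting: the consensus vocabulary is single-compartment.
- The pathway matrix applies no judgment to conflicting paralog
  localizations; it reports the set and lets the analyst decide.
- Band-ratio mode (height vs area) and the baseline anchors are choices;
  published values from other instruments are only comparable under the
  same convention.
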