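# Methods

`crc-deconv` classifies circulating rare cells found on enrichment-free
liquid-biopsy slides into epithelial circulating tumor cells (EPI.CTC),
partial-EMT tumor cells (pEMT.CTC) and circulating endothelial cells (CEC)
by fusing three evidence channels: immunofluorescence (IF) detection
statistics, single-cell copy-number profiles, and targeted-proteomics
(imaging mass cytometry, IMC) marker calls. This note records the models,
the defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Immunofluorescence detection

A slide frame is a leukocyte monolayer with at most a handful of rare
cells. Candidate rare cells are DAPI+/CK+/CD45−:

- **CK positivity (SDOM).** The cell's cytokeratin intensity is expressed
  in standard deviations over the mean of the surrounding leukocytes' CK
  signal, `(ck − mean(ref)) / sd(ref)` with the sample SD (n−1). The
  detection threshold is SDOM ≥ 6, closed at the boundary (a tie passes).
  Leukocytes act as the in-frame negative control, which makes the
  statistic invariant to affine intensity rescaling of the frame.
- **Reference population.** "Surrounding leukocytes" are all CD45+ cells of
  the frame. Because detection cannot use ground-truth labels, CD45+
  membership is `cd45 ≥ median(cd45)/2`: leukocytes outnumber rare cells by
  orders of magnitude, so the frame median sits inside the leukocyte CD45
  distribution and rare cells (CD45 ≈ 100× lower) never enter the
  reference. A per-neighbourhood reference is not implemented; the whole
  frame is the neighbourhood.
- **Auxiliary gates.** DAPI floor = leukocyte mean − 2 SD; CD45 ceiling =
  leukocyte 10th percentile. Both configurable.
- **Vimentin.** Scored positive when the raw fluorescent intensity (RFI)
  exceeds leukocyte mean + 2 SD of vimentin — a reference-relative rule
  parallel to the CK SDOM logic, since no absolute cutoff exists on the RFI
  scale. Positivity is monotone in the cutoff.
- **Eccentricity.** From the mask's central second moments: with
  eigenvalues λ1 ≥ λ2 of [[mu20, mu11], [mu11, mu02]], eccentricity is
  `sqrt(1 − λ2/λ1)` (0 = circle, →1 = line). Rotation- and
  scale-invariant by construction.

## Single-cell copy number

Reads are aggregated into 5,000 bins allocated to chromosomes by length
(largest remainder) and equal-width within a chromosome. The genome is
abstract — chromosome names/lengths are inputs — rather than a fixed build
with variable mappability bins; this keeps the module self-contained and
testable. Per cell:

1. **GC correction.** LOWESS of log count against bin GC fraction
   (span 0.3, zero-count bins floored at 0.5 reads); the fitted trend is
   divided out and the profile rescaled so the median ratio is exactly 1
   ("ratio to median").
2. **Segmentation (CBS).** Circular binary segmentation on log2 ratios,
   independently per chromosome. At each step the arc `[i, j)` maximizing
   `|S_arc| / (σ √(k(n−k)/n))` (centered values, global segment SD σ) is
   tested by permutation (default 1,000 permutations, α = 0.01, with the
   +1-corrected p-value and early stopping once significance is
   unreachable); accepted splits recurse. No "undo" pruning step is
   applied; instead adjacent segments closer than 0.1 log2 units are
   re-merged. Minimum segment width: 3 bins. Segments always partition the
   bin axis. Whether the original assay segments ratio or log-ratio space
   is not documented; log2 is used here and stated.
3. **State calling.** Segment mean ratio > 1.25 → gain, < 0.75 → loss,
   the closed interval [0.75, 1.25] → neutral. Calling never moves
   breakpoints.
4. **Clonality.** A cell's copy-number breakpoints are the bin indices
   where the *called state* changes between adjacent bins (so spurious
   mean-shift splits inside neutral regions never create breakpoints).
   Two altered cells share a breakpoint when positions differ by ≤ 2 bins
   (configurable); cells sharing ≥ 2 breakpoints (or all of them, for
   cells with fewer) are linked, and clonal groups are the transitive
   closure of links — grouping is symmetric and order-invariant. A lone
   altered cell can be flagged `cancer_typical_single` when a called
   gain/loss overlaps a user-supplied BED of cancer-typical regions; no
   oncology knowledge base is built in.

At the default study depth (500,000 reads over 5,000 bins ≈ 100
reads/bin), a single-copy event 30 bins wide is detected essentially
always; the permutation gate keeps the false-split rate on null
chromosomes at ≈ α per chromosome, and false splits that do survive are
called neutral and therefore never reach the clonality stage.

## Targeted proteomics

- **Relocation.** COIs from the IF scan are matched to IMC masks by greedy
  nearest-neighbour pairing under a distance gate; unmatched COIs are
  reported, duplicated coordinates raise an ambiguity warning.
- **Background.** Ion counts in the negative mask space (outside all cell
  masks) estimate a per-ROI, per-marker background that is subtracted from
  cell means and floored at zero (negative ion counts are unphysical).
- **Normalization.** Z-scores per marker against the ~150 reference
  leukocytes (`population="reference"`, the default): a marker's z-score
  then reads as SDs above the leukocyte background independently of the
  COI composition. A pooled mode (COIs + leukocytes) exists in config, but
  is not the default: if a fraction p of COIs genuinely express a marker,
  pooling pushes an expressing cell's z towards `sqrt((1−p)/p)` — at
  p ≈ 0.3 that is ≈ 1.5, i.e. exactly on the default positivity cutoff,
  and calling degenerates. Whether the original z-scores were computed per
  slide or per cohort is ambiguous; the normalization scope is simply the
  table passed in.
- **Positivity.** z ≥ 1.5 (closed; per-marker overrides). Convenience
  flags: `tissue_marker_positive` (any of ER/HER2/AR/PSA/PSMA present in
  the panel) and `endothelial_positive` (CD31). Markers absent from a
  slide's panel are carried as missing and never imputed. Note that a
  1.5-SD one-sided cutoff intrinsically calls ~7% of non-expressing cells
  positive; co-expression shares computed from the caller therefore run a
  few points above the true underlying fraction.

## Classification ladder

First match wins: (1) CD45+ → WBC; (2) clonal ∧ Vim− → EPI.CTC;
(3) clonal ∧ Vim+ → pEMT.CTC; (4) tissue-marker+ ∧ ¬CD31+ → EPI/pEMT by
Vim; (5) (copy-number neutral ∨ CD31+) ∧ Vim+ ∧ eccentricity ≥ 0.8 → CEC;
(6) CD31+ alone → CEC; otherwise unclassified. Cells with only IF evidence
stay unclassified — CK/Vim alone cannot separate the types. The elongation
cutoff 0.8 is a design choice (CECs are elongated, but no printed cutoff
exists) and is configurable. On contradictory evidence (clonal genome,
endothelial proteome) genomics wins — clonal copy-number alterations define
tumor lineage — and the conflict is flagged; such cells were never observed
in practice, so this rule is ours. Classification is a pure function of the
evidence bundle; each classification records a confidence tier naming the
omics that contributed.

Draw summaries report counts and fractions per label over classified rare
cells (WBC and unclassified excluded from the denominator; fractions sum
to 1 whenever any cell classified, and are flagged undefined otherwise).

## Statistics

Group comparisons use the tie-corrected Kruskal–Wallis omnibus test with
Dunn's pairwise rank z-tests, Bonferroni-adjusted over all pairs by default
(the adjustment is recorded in the output). The all-ties degenerate case
returns p = 1. Star annotations default to * ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001 and **** < 0.00001; the four-star band deliberately follows
the stricter printed convention and every threshold is configurable.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, with
ground truth attached:

- **Intensities** are log-normal per channel per label (non-negative,
  right-skewed). Leukocyte CK is mean 1.0 / SD 0.15, so the 6-SDOM boundary
  sits at ≈ 1.9 units; tumor CK means 3.2, CEC 2.6 ("CK dim" but
  detectable). Rare-cell DAPI (mean 13 vs leukocyte 10) reflects the larger
  nuclei of epithelial and endothelial cells and keeps true rare cells
  above the leukocyte-derived DAPI floor — the generator is deliberately
  calibrated so that ground-truth rare cells pass the default detection
  gates; detection sensitivity against these defaults is a pipeline check,
  not a biological claim.
- **Vimentin.** pEMT cells draw RFI log-uniformly on the printed Vim+
  clonal range [0.0032, 0.0522]; EPI cells draw from the leukocyte
  baseline (the printed Vim− *observed* range overlaps the Vim+ range and
  is not a generative model for negatives); CEC vimentin is high.
- **Morphology.** Eccentricity uniform per label (leukocytes/tumor cells
  round, 0.10–0.60; CECs elongated, 0.85–0.97); masks are ellipses whose
  central moments are derived analytically at a random orientation.
- **Copy number.** One clonal template shared by all tumor cells of a draw
  (focal events of 30–60 bins, copy number 1/3/4, neutral flanks, on 3
  chromosomes); CECs and leukocytes are diploid. Binned counts are Poisson
  (optionally negative-binomial, dispersion 0.1 — mild overdispersion
  typical of whole-genome-amplified single cells) around expectations
  proportional to copy number × bin width × a log-linear GC bias
  `exp(strength · (gc − 0.45))`, normalized to 500,000 reads/cell.
- **IMC.** Expressing cells draw marker signal at 4–8 ions/pixel with 25%
  CV; non-expressing cells sit at the leukocyte baseline (0.05); EpCAM is
  elevated in an exact 50% subfraction of tumor cells by default; additive
  Poisson background (0.1 ions/pixel) contaminates every mask and is
  observable in negative mask space.
- **Compositions.** The four-draw index-patient scenario uses ~90% CTC at
  active disease and ~75% CEC at stable disease, with 40% of clonal cells
  vimentin-positive. Spike-in frames place exactly
  `round(concentration × volume)` endothelial-profile cells on a
  normal-donor background.
- **Determinism.** A single master seed fans out to named, independent
  child streams (frame / reads / clone / imc / spike), so adding one
  generator never perturbs another and equal seeds give byte-identical
  tables.

What the generator does **not** emulate: pixel-level image content and
segmentation errors, cell doublets and clusters, staining batch effects,
mappability/replication-timing coverage structure, WGA amplicon dropout
beyond overdispersion, isotope spillover, and panel drift between slides.
Tests passing on synthetic data therefore validate the statistical
machinery and the decision logic — not performance on patient slides.

## Problem sizes and tolerances

Unit tests run scaled-down conditions (hundreds of bins, tens of cells);
pipeline-level checks run the study conditions (n = 200 rare cells, 5,000
bins, 500,000 reads/cell) with 200 CBS permutations, completing in a
couple of minutes on one CPU. Composition checks accept the recovered
fraction within the binomial 95% CI of the generated composition at the
stated n. Monte-Carlo-valued checks (CBS null false-split rate, the
Kruskal–Wallis permutation cross-check) use explicit sampling-error
bounds stated in the tests.

## Known limitations

- CBS uses a global-SD arc statistic without the original "undo" pruning;
  on very short chromosomes (< 6 bins) no splits are attempted.
- Clonality compares breakpoint positions only, not segment states or
  levels; two clones with coincidentally aligned breakpoints would merge.
- The IMC positivity caller's false-positive tail (see above) biases
  co-expression shares upward by a few points at the default cutoff.
- The decision ladder trusts upstream calls; it propagates, rather than
  models, their uncertainty.
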