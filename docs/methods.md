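# Methods

## Pipeline model and assumptions

The package operates on an aligned MS1 feature table: one (m/z, RT) row
per feature with per-sample intensities and sample roles (study
replicates vs matrix blanks). It assumes peak picking, alignment and
gap filling have already happened upstream; retention time is in
seconds internally, with minutes converted only at I/O boundaries (mzML
scan start times declare their unit, the scheduler window is exposed in
minutes on the CLI).

The central assumption is that one compound produces several co-eluting
features whose pairwise m/z distances recur across the whole run, and
whose intensities co-vary across study samples. Both redundancy signals
are used: recurrent paired mass distances (PMDs) connect features into
pseudo-spectra, and intensity correlation prunes coincidental members.

## QC filters

| parameter | default | meaning |
|---|---|---|
| rt_min / rt_max | 30 / 930 s | drop void volume and wash phase (inclusive) |
| fold | 3 | study mean ≥ fold × pooled blank mean |
| rsd_max | 0.30 | study-sample RSD (sd/mean, ddof=1) |

Boundary semantics remove strict violators only: a feature at exactly
fold change 3 or RSD 30% is retained. Fold change uses arithmetic means
of raw intensities over all pooled blanks; a feature absent from every
blank is kept without forming a ratio. Features with zero study mean
are removed by the RSD filter (undefined RSD, unusable precursor).
Both boundary comparisons carry a 1e-9 relative guard against float
round-off. The three filters each return a subset of the input features
and commute.

## PMD reduction

* **RT grouping** — hierarchical clustering of RT cut at 10 s. The
  default linkage is *complete* (group diameter ≤ cutoff): with
  hundreds of compounds over a ~900 s gradient, consecutive features
  are almost everywhere closer than any sensible cutoff, so
  single-linkage (nearest-neighbour chaining) would collapse the whole
  run into one group and make per-group frequency counting meaningless.
  The linkage method remains an argument for experimentation.
* **PMD frequency** — every within-group unordered pair contributes
  |Δm/z| rounded to two decimals (half away from zero, with a 1e-7
  guard for binary representation of .xx5 boundaries); a PMD counts at
  most once per RT group, so frequency = number of groups containing it.
* **High-frequency selection** — explicit cutoff, or automatic elbow:
  cut at the largest drop in the descending sequence of distinct
  frequencies, never keeping PMDs seen in fewer than 2 groups. The
  elbow avoids a magic constant; on data with planted adduct/loss
  offsets the true PMDs sit far above the coincidental background.
* **Components and independent peaks** — within each RT group, edges
  connect pairs at a high-frequency PMD; each connected component
  yields one independent peak, the member with maximal mean study
  intensity (ties: lower m/z, then id — the same rule used for
  precursor election).
* **Merging** — clusters sharing any member are merged (union-find);
  the merged base peak is the most intense of the merged bases.
* **Correlation pruning** — members with Pearson r < 0.9 against the
  base peak's study-intensity vector are dropped (boundary r = 0.9
  kept, 1e-12 absolute guard). Correlation is member-vs-base, not
  all-pairs: the base peak is the cluster's anchor, and member-vs-base
  is the standard pseudo-spectrum criterion; correlating scalar mass
  distances across samples is not defined. With fewer than 3 study
  samples pruning is skipped with a warning; zero-variance members are
  removed with a warning.

## Injection scheduling

Targets are shuffled with a seeded generator and placed first-fit into
the lowest-index injection where every sliding RT window of 12 s
(0.2 min) still holds ≤ 6 targets, opening a new injection when none
fits. Sliding windows — not fixed bins — are the stricter reading of a
"within a retention time shift" constraint and are what the validator
checks by brute force. First-fit after random shuffle keeps the
randomized character of the assignment while guaranteeing validity; for
fully co-eluting inputs it achieves the analytic lower bound
ceil(n / max_per_window). Exported inclusion lists carry rt ± half the
window, floored at 0 s.

## Polarity linking

[M+H]⁺ and [M−H]⁻ of one neutral differ by 2 × 1.00728 = 2.01456 Da
(electron-corrected proton mass). The conventional label for this gap
rounds it to 2.02, so the default acceptance window is [2.0046, 2.0246]
Da — ±0.01 Da around the physical value, wide enough to cover the
nominal convention as well. RT tolerance is 10 s, boundary inclusive.
A feature may appear in several links; disambiguation is left to
downstream annotation. The linkage presumes both polarities were
acquired on the same column and gradient.

## Consensus MS2

Scans are assigned to the nearest target within 0.02 Da of precursor
m/z (ties to the lower-m/z target); an optional RT gate is off by
default because precursor selection already localises targets in m/z.
Pooled fragments are single-linkage clustered on m/z with merges below
5 ppm; ppm is always computed relative to the smaller of the two m/z
values. A fragment cluster is kept iff present in strictly more than
60% of the scans — the comparison uses exact rational arithmetic
(`Fraction`), so 3 of 5 scans is dropped and 4 of 5 kept regardless of
binary float representation. "More than 60% of scans" is an occurrence
criterion; an intensity reading of the same threshold is not
well-defined and was rejected. Retained fragments report the
intensity-weighted mean m/z and the median per-scan intensity (a scan
contributing several peaks to one cluster contributes their sum). A
single scan passes through unchanged. Known-compound matching uses
theoretical m/z = mass ± 1.00728 Da and equality after rounding both
values to two decimals, half away from zero.

## Synthetic data generator

The generator emulates a five-replicate + five-blank reference-material
design: 300 compounds, 3 ions each (base, Na adduct +21.9819, water
loss −18.0106; the 13C offset +1.0034 is used when more ions are
requested), RT uniform in [32, 928] s, base m/z uniform inside
[100, 1000] Da with margins for the offsets, abundance lognormal
(median 1e6, log-sd 1), redundant-ion ratios uniform in [0.2, 0.8] so
the base ion is always the most intense true ion.

Intensity structure: study intensity = abundance × ion ratio ×
per-sample abundance pattern × multiplicative lognormal noise
(CV 5%). The pattern is a per-compound random permutation of a fixed
standardized profile scaled to an exact sample CV of 18%, shared by all
of the compound's ions; 80% of the noise *variance* is likewise shared
among the compound's ions within a sample (matrix/ionization effects),
with the rest ion-specific. This split is deliberate: with five
samples, fully ion-independent 5% noise cannot push the sample Pearson
correlation above 0.9 at the ~99% rate the pruning threshold presumes
while keeping replicate RSD under the 30% QC limit — the required
across-sample signal CV would itself violate the RSD filter. Partially
shared technical noise is the physically standard resolution; with
these defaults, measured over 10⁵ simulated compounds, within-compound
pairs fall below r = 0.9 at ~2×10⁻⁴ and true ions exceed 30% RSD at
~10⁻⁵.

Background features split between blank-like rows (blank ≈ study
intensity; removed by the fold-change filter) and irreproducible rows
(study log-sd 0.9, empty blanks; removed by the RSD filter). Shared
compounds appear in both polarities at base m/z difference 2.01456 Da
and RT jitter ≤ 2 s; each polarity's remaining compounds are unrelated.
MS2 simulation emits per-target repeat scans with true fragments
jittered ≤ 2 ppm plus scan-specific spurious peaks
(Binomial(n_fragments, rate) per scan).

Not modelled: chromatographic peak shapes, isotope fine structure,
detector saturation, inter-batch drift, real adduct chemistry beyond
fixed offsets. Passing tests therefore demonstrate the algorithmic
contracts (grouping, counting, election, scheduling, merging) under the
assumed statistical structure, not performance on instrument data —
in particular, real replicate designs can show weaker within-compound
correlation than the generator produces.

## Problem sizes

The default synthetic dataset (1100 features per polarity) runs the
full pipeline in ~2 s; the test suite uses that scale throughout, with
oracle comparisons (brute-force transitive closure, all-pairs consensus
clustering) on random instances of ≤ 12 features / ≤ 10 scans where
exhaustive enumeration is exact.

## Known limitations

* The PMD frequency elbow can under-select when all PMDs have similar
  frequencies (flat curve); an explicit cutoff is then preferable.
* Scan grouping ignores RT by default; co-isobaric targets at different
  RTs need the optional RT gate.
* The polarity link window accepts both the physical and the nominal
  proton-pair difference; on very dense tables this admits occasional
  coincidental pairs, which downstream MS2 annotation must resolve.
* `read_ms2_runs` implements a self-contained subset of PSI mzML
  (centroided spectra, 32/64-bit float arrays, zlib or none); exotic
  encodings (numpress) are not supported.
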