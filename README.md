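# pmdda

Paired-mass-distance dependent acquisition: precursor-ion selection,
targeted-MS/MS injection scheduling, cross-polarity feature linking and
consensus MS2 extraction for untargeted LC-HRMS metabolomics.

## The problem

An untargeted full-scan (MS1) metabolomics run measures thousands of
features, but one compound rarely yields one feature: sodium adducts,
isotopologues, in-source water loss and other redundant ions spread each
compound over several co-eluting peaks. Fragmenting every feature is
impossible within one injection, and fragmenting redundant ions wastes
instrument time. `pmdda` turns an aligned MS1 feature table into a small,
study-specific list of precursor ions — one per putative compound —
and schedules them into repeat injections for targeted MS/MS, without a
predefined adduct list.

## Method

For features grouped by retention time (co-elution candidates), every
within-group pairwise mass distance Δm = |m/z_i − m/z_j| is rounded to
two decimals and tabulated across groups. Distances that recur in many
RT groups (e.g. 21.98 Da for Na/H exchange, 18.01 Da for water loss) are
data-driven signatures of redundant ions. Within each RT group, feature
pairs at a high-frequency PMD are connected; each connected component is
one pseudo-spectrum whose most intense member is its *independent peak*.
Clusters sharing ions are merged, members whose study-sample intensity
profile has Pearson r < 0.9 with the base peak are pruned, and the most
intense remaining member becomes the MS/MS precursor.

Around that core:

* **QC filters** — RT range [30, 930] s, study/blank mean fold change ≥ 3,
  study RSD ≤ 30%.
* **Scheduler** — seeded random first-fit partition of precursors into
  injections such that no sliding 0.2-min RT window of any injection
  holds more than 6 targets.
* **Polarity linking** — positive and negative-mode features differing by
  ~2.015 Da ([M+H]⁺ vs [M−H]⁻) within 10 s RT are candidate same-compound
  pairs.
* **Consensus MS2** — repeat scans are grouped per target (precursor
  within 0.02 Da), fragments aligned at < 5 ppm, and a fragment is kept
  only when present in > 60% of the scans.

A fully seeded synthetic-data generator (`pmdda.simulate`) produces
ground-truth datasets with redundant ions, correlated intensity
profiles, blank background and fragment scans, so the whole pipeline is
testable without instrument data.

## Worked example

```sh
$ pmdda simulate sim --seed 1 --n-compounds 50 --background 40 --with-ms2
pos: 190 features, neg: 190 features
wrote 150 MS2 scans for 50 targets

$ pmdda filter sim/pos.csv filtered.csv
190 -> 151 features

$ pmdda precursors filtered.csv precursors.csv clusters.json
151 features -> 51 independent peaks -> 51 precursors (high-frequency PMDs: 3)

$ pmdda schedule precursors.csv inj/ --seed 42
51 targets -> 1 injections in inj/

$ pmdda filter sim/neg.csv filtered_neg.csv
190 -> 150 features

$ pmdda link-modes filtered.csv filtered_neg.csv links.csv
75 cross-polarity links

$ pmdda extract-ms2 precursors.csv sim/ms2_pos.mzML --out-mgf consensus.mgf
150 scans -> 50 consensus spectra (0 scans unassigned)
```

Reading the numbers: the 50 simulated compounds × 3 ions plus 40
background features give 190 raw features; QC filtering removes 39 of
the 40 background rows (151 left). PMD reduction collapses the 150 true
ions into 50 compound clusters (plus one background survivor), electing
51 precursors. At this density one injection satisfies the 6-per-0.2-min
constraint. The 75 cross-polarity links are the 25 shared compounds × 3
ion pairs each, and every precursor's repeat scans merge into one
consensus spectrum in the MGF.

The same steps are available as library calls
(`simulate_dataset`, `apply_qc_filters`, `pick_precursors`,
`schedule_injections`, `link_polarities`, `extract_consensus_spectra`).

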