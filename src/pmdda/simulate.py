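"""Ground-truth synthetic LC-MS datasets for end-to-end testing.

The generator emulates the statistical structure the pipeline relies on,
for a replicate design of study samples plus matrix blanks:

* each compound emits a base ion plus redundant ions at fixed mass
  offsets (Na/H exchange +21.9819 Da, water loss -18.0106 Da, 13C
  isotope +1.0034 Da), co-eluting within ~1 s;
* study intensities are compound abundance x ion ratio x a per-sample
  abundance pattern x multiplicative lognormal noise. Most of the noise
  variance is shared among a compound's ions within a sample (matrix /
  ionization effects), so within-compound intensity vectors correlate
  strongly across samples while replicate RSD stays inside QC limits;
* blank intensities for compound ions are near zero; background features
  either mirror their study intensity in the blanks (fail the fold-change
  filter) or fluctuate wildly across replicates (fail the RSD filter);
* a configurable fraction of compounds ionises in both polarities at the
  same retention time (jitter <= 2 s) with base m/z differing by two
  proton masses; the rest of each polarity's compounds are unrelated.

No chromatographic peak shapes, isotope fine structure or detector
saturation are modelled: passing tests demonstrate the algorithmic
contracts, not instrument realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FeatureTable, MS2Scan, SampleInfo, ROLE_BLANK, ROLE_STUDY

#: [M+H]+ minus [M-H]- in Da (two electron-corrected protons)
_POS_NEG_DELTA = 2.01456

DEFAULT_OFFSETS = (
    (21.9819, "Na"),      # Na/H exchange adduct
    (-18.0106, "H2O"),    # neutral loss of water
    (1.0034, "13C"),      # first isotopologue
)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults emulate a five-replicate, five-blank reference-material
    design with 300 compounds carrying 3 redundant ions each, eluting
    between 30 and 930 s in a 100-1000 Da window.
    """

    n_compounds: int = 300
    ions_per_compound: int = 3
    n_study: int = 5
    n_blank: int = 5
    rt_range: tuple[float, float] = (30.0, 930.0)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    offset_table: tuple[tuple[float, str], ...] = DEFAULT_OFFSETS
    noise_cv: float = 0.05
    background_features: int = 200
    shared_fraction: float = 0.5
    abundance_cv: float = 0.18       # across-sample abundance pattern CV
    shared_noise_frac: float = 0.8   # fraction of noise variance shared within a compound
    n_decoys: int = 0                # co-eluting decoy compounds (correlation-pruning stressor)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.ions_per_compound, self.n_study, self.n_blank) < 1:
            raise ValueError("counts must be positive")
        if self.ions_per_compound - 1 > len(self.offset_table):
            raise ValueError("not enough mass offsets for ions_per_compound")
        offs = [o for o, _ in self.offset_table[: self.ions_per_compound - 1]]
        lo = self.mz_range[0] - min(offs + [0.0]) + _POS_NEG_DELTA
        hi = self.mz_range[1] - max(offs + [0.0])
        if lo >= hi:
            raise ValueError("mass offsets leave no feasible base m/z range")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Synthetic compound -> feature / fragment bookkeeping.

    feature_compound maps every non-background feature id to its compound
    id; background ids are listed separately. best_ion records, per
    (polarity, compound), the feature expected to win precursor election
    (the base ion — its intensity ratio is maximal by construction).
    """

    feature_compound: dict[str, str] = field(default_factory=dict)
    ion_label: dict[str, str] = field(default_factory=dict)
    best_ion: dict[tuple[str, str], str] = field(default_factory=dict)
    fragments: dict[str, list[float]] = field(default_factory=dict)
    shared: dict[str, tuple[str, str]] = field(default_factory=dict)
    background_ids: set[str] = field(default_factory=set)

    def compound_of(self, feature_id: str) -> str:
        """Compound id, treating each background feature as its own unit."""
        return self.feature_compound.get(feature_id, f"bg:{feature_id}")

    def compounds(self, polarity: str) -> set[str]:
        return {cid for pol, cid in self.best_ion if pol == polarity}

    def to_json(self, path) -> None:
        payload = {
            "feature_compound": self.feature_compound,
            "ion_label": self.ion_label,
            "best_ion": {f"{p}|{c}": f for (p, c), f in self.best_ion.items()},
            "fragments": self.fragments,
            "shared": {c: list(v) for c, v in self.shared.items()},
            "background_ids": sorted(self.background_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_compound=d["feature_compound"],
            ion_label=d["ion_label"],
            best_ion={tuple(k.split("|", 1)): v for k, v in d["best_ion"].items()},
            fragments={k: list(v) for k, v in d["fragments"].items()},
            shared={k: tuple(v) for k, v in d["shared"].items()},
            background_ids=set(d["background_ids"]),
        )


def _samples(cfg: SynthConfig) -> list[SampleInfo]:
    return [SampleInfo(f"study{i + 1}", ROLE_STUDY) for i in range(cfg.n_study)] + [
        SampleInfo(f"blank{i + 1}", ROLE_BLANK) for i in range(cfg.n_blank)
    ]


def _abundance_pattern(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Per-sample relative abundance with exact sample CV = abundance_cv."""
    if cfg.n_study < 2:
        return np.ones(cfg.n_study)
    base = np.linspace(-1.0, 1.0, cfg.n_study)
    base = (base - base.mean()) / base.std(ddof=1)
    return 1.0 + cfg.abundance_cv * rng.permutation(base)


def _compound_block(
    rng: np.random.Generator,
    cfg: SynthConfig,
    cid: str,
    polarity: str,
    base_mz: float,
    base_rt: float,
    truth: GroundTruth,
) -> list[dict]:
    """Rows for one compound's ions in one polarity."""
    var = np.log1p(cfg.noise_cv**2)
    s_shared = np.sqrt(var * cfg.shared_noise_frac)
    s_ion = np.sqrt(var * (1.0 - cfg.shared_noise_frac))
    abundance = rng.lognormal(np.log(1e6), 1.0)
    pattern = _abundance_pattern(rng, cfg)
    shared_noise = rng.lognormal(-s_shared**2 / 2, s_shared, cfg.n_study)

    labels = ["M"] + [lab for _, lab in cfg.offset_table[: cfg.ions_per_compound - 1]]
    offsets = [0.0] + [off for off, _ in cfg.offset_table[: cfg.ions_per_compound - 1]]
    ratios = [1.0] + list(rng.uniform(0.2, 0.8, cfg.ions_per_compound - 1))

    rows = []
    for label, offset, ratio in zip(labels, offsets, ratios):
        fid = f"{polarity}_{cid}_{label}"
        ion_noise = rng.lognormal(-s_ion**2 / 2, s_ion, cfg.n_study)
        study = abundance * ratio * pattern * shared_noise * ion_noise
        blank = abundance * ratio * rng.uniform(0.0, 0.002, cfg.n_blank)
        rows.append(
            {
                "id": fid,
                "mz": base_mz + offset,
                "rt": base_rt + rng.uniform(-0.5, 0.5),
                "intensities": np.concatenate([study, blank]),
            }
        )
        truth.feature_compound[fid] = cid
        truth.ion_label[fid] = label
    truth.best_ion[(polarity, cid)] = f"{polarity}_{cid}_M"
    return rows


def _background_rows(
    rng: np.random.Generator, cfg: SynthConfig, polarity: str, truth: GroundTruth
) -> list[dict]:
    rows = []
    for b in range(cfg.background_features):
        fid = f"{polarity}_bg{b:04d}"
        level = rng.lognormal(np.log(1e5), 1.0)
        if b % 2 == 0:  # blank-like background: fails the fold-change filter
            study = level * rng.lognormal(0, 0.2, cfg.n_study)
            blank = level * rng.lognormal(0, 0.2, cfg.n_blank)
        else:  # irreproducible background: fails the RSD filter
            study = level * rng.lognormal(0, 0.9, cfg.n_study)
            blank = np.zeros(cfg.n_blank)
        rows.append(
            {
                "id": fid,
                "mz": rng.uniform(*cfg.mz_range),
                "rt": rng.uniform(*cfg.rt_range),
                "intensities": np.concatenate([study, blank]),
            }
        )
        truth.background_ids.add(fid)
    return rows


def _to_table(rows: list[dict], samples: list[SampleInfo]) -> FeatureTable:
    return FeatureTable(
        ids=[r["id"] for r in rows],
        mz=[r["mz"] for r in rows],
        rt=[r["rt"] for r in rows],
        intensities=np.vstack([r["intensities"] for r in rows]),
        samples=samples,
    )


def simulate_dataset(cfg: SynthConfig = SynthConfig()) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Generate positive- and negative-mode feature tables plus ground truth.

    Each table holds ``n_compounds`` compounds x ``ions_per_compound``
    features plus ``background_features`` background rows. The first
    ``shared_fraction`` of positive-mode compounds also appear in negative
    mode (base m/z lower by 2.01456 Da, RT jitter <= 2 s); the remaining
    negative-mode compounds are unrelated. Fully deterministic for a
    given config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    samples = _samples(cfg)

    offs = [0.0] + [o for o, _ in cfg.offset_table[: cfg.ions_per_compound - 1]]
    mz_lo = cfg.mz_range[0] - min(offs) + _POS_NEG_DELTA
    mz_hi = cfg.mz_range[1] - max(offs)
    rt_lo, rt_hi = cfg.rt_range[0] + 2.0, cfg.rt_range[1] - 2.0

    n_shared = int(round(cfg.shared_fraction * cfg.n_compounds))
    pos_rows: list[dict] = []
    neg_rows: list[dict] = []

    for c in range(cfg.n_compounds):
        cid = f"C{c:04d}"
        base_mz = rng.uniform(mz_lo, mz_hi)
        base_rt = rng.uniform(rt_lo, rt_hi)
        pos_rows += _compound_block(rng, cfg, cid, "pos", base_mz, base_rt, truth)
        if c < n_shared:
            neg_mz = base_mz - _POS_NEG_DELTA
            neg_rt = base_rt + rng.uniform(-2.0, 2.0)
            neg_rows += _compound_block(rng, cfg, cid, "neg", neg_mz, neg_rt, truth)
            truth.shared[cid] = (f"pos_{cid}_M", f"neg_{cid}_M")

    for c in range(cfg.n_compounds - n_shared):
        cid = f"N{c:04d}"
        neg_rows += _compound_block(
            rng, cfg, cid, "neg", rng.uniform(mz_lo, mz_hi), rng.uniform(rt_lo, rt_hi), truth
        )

    for d in range(cfg.n_decoys):
        # decoy rides on a host compound's RT with an independent profile:
        # the hard case the correlation-pruning threshold exists for
        cid = f"D{d:04d}"
        host_rt = pos_rows[(d * cfg.ions_per_compound) % len(pos_rows)]["rt"]
        pos_rows += _compound_block(
            rng, cfg, cid, "pos", rng.uniform(mz_lo, mz_hi), host_rt, truth
        )

    pos_rows += _background_rows(rng, cfg, "pos", truth)
    neg_rows += _background_rows(rng, cfg, "neg", truth)

    for cid in sorted(truth.compounds("pos") | truth.compounds("neg")):
        n_frag = int(rng.integers(4, 9))
        truth.fragments[cid] = sorted(rng.uniform(50.0, 900.0, n_frag).tolist())

    return _to_table(pos_rows, samples), _to_table(neg_rows, samples), truth


def simulate_ms2_runs(
    precursors: pd.DataFrame,
    truth: GroundTruth,
    n_scans_per_target: int = 3,
    spurious_rate: float = 0.1,
    mz_jitter_ppm: float = 2.0,
    seed: int = 0,
    source_run: str = "synthetic",
) -> list[MS2Scan]:
    """Fragment scans for precursor targets, with known true fragments.

    Each target yields ``n_scans_per_target`` scans at its RT carrying the
    compound's true fragments (m/z jitter <= ``mz_jitter_ppm``) plus
    scan-specific spurious peaks: per scan, Binomial(n_true, spurious_rate)
    random fragments that never repeat across scans. A precursor absent
    from the ground truth yields scans of purely random fragments
    (negative control).
    """
    rng = np.random.default_rng(seed)
    scans: list[MS2Scan] = []
    for p in precursors.itertuples():
        cid = truth.feature_compound.get(str(p.id))
        frags = truth.fragments.get(cid) if cid is not None else None
        if frags is None:
            base_mz = np.array([])
        else:
            base_mz = np.asarray(frags, dtype=float)
        base_int = rng.lognormal(np.log(1e4), 0.5, base_mz.size)
        for _ in range(n_scans_per_target):
            if base_mz.size:
                jitter = rng.uniform(-mz_jitter_ppm, mz_jitter_ppm, base_mz.size) * 1e-6
                mz = base_mz * (1.0 + jitter)
                inten = base_int * rng.lognormal(0, 0.3, base_mz.size)
                n_spur = int(rng.binomial(base_mz.size, spurious_rate))
            else:
                mz = np.array([])
                inten = np.array([])
                n_spur = 5
            spur_mz = rng.uniform(20.0, max(float(p.mz), 50.0), n_spur)
            spur_int = rng.lognormal(np.log(2e3), 0.5, n_spur)
            scans.append(
                MS2Scan(
                    precursor_mz=float(p.mz) + rng.uniform(-0.005, 0.005),
                    rt=float(p.rt) + rng.uniform(-2.0, 2.0),
                    mz=np.concatenate([mz, spur_mz]),
                    intensity=np.concatenate([inten, spur_int]),
                    source_run=source_run,
                )
            )
    return scans


def ground_truth_report(
    truth: GroundTruth,
    clusters=None,
    precursors: pd.DataFrame | None = None,
    polarity: str = "pos",
    links: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the generator's ground truth.

    cluster_purity
        fraction of clusters whose members all map to one compound
        (each background feature counts as its own unit).
    compound_recall
        fraction of this polarity's compounds hit by >= 1 precursor.
    precursor_correctness
        fraction of compound-mapped precursors that are their compound's
        most intense true ion.
    link_recall / link_precision
        compound-level agreement of cross-polarity links with the
        shared-compound map (only when ``links`` is given).
    """
    metrics: dict[str, float] = {}
    if clusters is not None:
        pure = sum(
            1 for c in clusters if len({truth.compound_of(m) for m in c.members}) == 1
        )
        metrics["cluster_purity"] = pure / len(clusters) if clusters else float("nan")
    if precursors is not None:
        universe = truth.compounds(polarity)
        hit = set()
        correct = 0
        mapped = 0
        for p in precursors.itertuples():
            cid = truth.feature_compound.get(str(p.id))
            if cid is None:
                continue
            mapped += 1
            hit.add(cid)
            if truth.best_ion.get((polarity, cid)) == str(p.id):
                correct += 1
        metrics["compound_recall"] = len(hit & universe) / len(universe) if universe else float("nan")
        metrics["precursor_correctness"] = correct / mapped if mapped else float("nan")
    if links is not None:
        true_pairs = set(truth.shared)
        pred_ok = 0
        hit_compounds = set()
        for row in links.itertuples():
            cp = truth.feature_compound.get(str(row.pos_id))
            cn = truth.feature_compound.get(str(row.neg_id))
            if cp is not None and cp == cn and cp in true_pairs:
                pred_ok += 1
                hit_compounds.add(cp)
        metrics["link_recall"] = len(hit_compounds) / len(true_pairs) if true_pairs else float("nan")
        metrics["link_precision"] = pred_ok / len(links) if len(links) else float("nan")
    for v in metrics.values():
        assert np.isnan(v) or 0.0 <= v <= 1.0
    return metrics
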