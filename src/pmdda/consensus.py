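"""Consensus MS2 extraction, MS1 linking, and known-compound matching.

Each precursor target is fragmented in several repeat scans; the scans
are first grouped per target (precursor m/z within 0.02 Da, optionally
an RT gate), then merged into one consensus spectrum: fragment peaks
across scans are clustered when their m/z agree within 5 ppm, and a
fragment cluster is retained only when it appears in strictly more than
60% of the contributing scans — irreproducible (noise) peaks drop out.

ppm throughout this module is computed relative to the *smaller* of the
two compared m/z values, and tolerance boundaries are strict (< 5 ppm
merges / links, exactly 5 ppm does not).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io import FeatureTable, MS2Scan

#: electron-corrected proton mass, Da; added/subtracted for [M+H]+/[M-H]-
PROTON_MASS = 1.00728


@dataclass
class ConsensusSpectrum:
    """Merged fragment spectrum for one precursor target."""

    target_feature: str
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    n_scans: int

    @property
    def fragments(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def n_fragments(self) -> int:
        return int(np.asarray(self.mz).size)


def ppm_shift(a: float, b: float) -> float:
    """|a - b| in parts-per-million of the smaller value."""
    return abs(a - b) / min(a, b) * 1e6


def group_scans_by_precursor(
    scans: list[MS2Scan],
    targets: pd.DataFrame,
    mz_tol: float = 0.02,
    rt_tol: float | None = None,
) -> tuple[dict[str, list[MS2Scan]], list[MS2Scan]]:
    """Assign each scan to the nearest-m/z target within tolerance.

    ``targets`` needs id/mz columns (rt required only when ``rt_tol`` is
    set). A scan within ``mz_tol`` of several targets goes to the one
    with the smallest m/z difference; exact ties go to the lower-m/z
    target. Returns (target id -> scans, unassigned scans).
    """
    assigned: dict[str, list[MS2Scan]] = {str(t): [] for t in targets["id"]}
    unassigned: list[MS2Scan] = []
    recs = list(targets.itertuples())
    for scan in scans:
        best = None
        for t in recs:
            dmz = abs(scan.precursor_mz - float(t.mz))
            if dmz > mz_tol:
                continue
            if rt_tol is not None and abs(scan.rt - float(t.rt)) > rt_tol:
                continue
            key = (dmz, float(t.mz), str(t.id))
            if best is None or key < best[0]:
                best = (key, str(t.id))
        if best is None:
            unassigned.append(scan)
        else:
            assigned[best[1]].append(scan)
    return assigned, unassigned


def build_consensus_spectrum(
    scans: list[MS2Scan],
    target_feature: str = "",
    frag_ppm: float = 5.0,
    occurrence_min: float = 0.6,
) -> ConsensusSpectrum:
    """Merge repeat scans of one precursor into a consensus spectrum.

    Pooled fragments are single-linkage clustered on m/z: sorted peaks
    chain together while consecutive gaps are < ``frag_ppm`` ppm. A
    cluster is kept iff it occurs in strictly more than ``occurrence_min``
    of the scans (exact-fraction comparison, so 3 of 5 scans at the 60%
    default is dropped and 4 of 5 kept). Retained fragments report the
    intensity-weighted mean m/z and the median of per-scan intensities
    (a scan contributing several peaks to one cluster contributes their
    sum). A single scan passes through unchanged.
    """
    if not scans:
        raise ValueError("cannot build a consensus spectrum from zero scans")
    n_scans = len(scans)
    pool = [
        (m, i, s_idx)
        for s_idx, scan in enumerate(scans)
        for m, i in zip(scan.mz, scan.intensity)
    ]
    pool.sort(key=lambda t: t[0])

    clusters: list[list[tuple[float, float, int]]] = []
    for frag in pool:
        if clusters and ppm_shift(clusters[-1][-1][0], frag[0]) < frag_ppm:
            clusters[-1].append(frag)
        else:
            clusters.append([frag])

    occ = Fraction(str(occurrence_min))
    out_mz, out_int = [], []
    for cluster in clusters:
        present = {s for _, _, s in cluster}
        if Fraction(len(present), n_scans) <= occ:
            continue
        mzs = np.array([m for m, _, _ in cluster])
        ints = np.array([i for _, i, _ in cluster])
        weights = ints if ints.sum() > 0 else np.ones_like(ints)
        per_scan = {}
        for _, i, s in cluster:
            per_scan[s] = per_scan.get(s, 0.0) + i
        out_mz.append(float(np.average(mzs, weights=weights)))
        out_int.append(float(np.median(list(per_scan.values()))))

    order = np.argsort(out_mz, kind="stable")
    return ConsensusSpectrum(
        target_feature=target_feature,
        precursor_mz=float(np.median([s.precursor_mz for s in scans])),
        rt=float(np.median([s.rt for s in scans])),
        mz=np.asarray(out_mz)[order],
        intensity=np.asarray(out_int)[order],
        n_scans=n_scans,
    )


def extract_consensus_spectra(
    scans: list[MS2Scan],
    targets: pd.DataFrame,
    mz_tol: float = 0.02,
    rt_tol: float | None = None,
    frag_ppm: float = 5.0,
    occurrence_min: float = 0.6,
) -> tuple[list[ConsensusSpectrum], list[MS2Scan]]:
    """Group scans per target and build one consensus spectrum each.

    Targets without any matching scan are omitted. Convenience wrapper
    around :func:`group_scans_by_precursor` and
    :func:`build_consensus_spectrum`.
    """
    grouped, unassigned = group_scans_by_precursor(scans, targets, mz_tol, rt_tol)
    spectra = []
    by_id = {str(t.id): t for t in targets.itertuples()}
    for tid, tscans in grouped.items():
        if not tscans:
            continue
        spec = build_consensus_spectrum(tscans, tid, frag_ppm, occurrence_min)
        spec.rt = float(by_id[tid].rt) if hasattr(by_id[tid], "rt") else spec.rt
        spectra.append(spec)
    return spectra, unassigned


def link_back_to_ms1(
    entries,
    table: FeatureTable,
    ppm: float = 5.0,
    rt_tol: float = 5.0,
) -> pd.DataFrame:
    """Attach spectra/annotations to MS1 features by m/z (ppm) and RT.

    ``entries`` is a DataFrame with mz/rt (and optionally id) columns, or
    a list of consensus spectra. An entry links to *every* feature with
    m/z shift strictly below ``ppm`` and RT shift strictly below
    ``rt_tol`` seconds; entries without any match appear once with
    ``feature_id`` NA (flagged unmatched).
    """
    if not isinstance(entries, pd.DataFrame):
        entries = pd.DataFrame(
            {
                "id": [s.target_feature for s in entries],
                "mz": [s.precursor_mz for s in entries],
                "rt": [s.rt for s in entries],
            }
        )
    if "id" not in entries.columns:
        entries = entries.assign(id=[f"E{i + 1:04d}" for i in range(len(entries))])
    rows = []
    for e in entries.itertuples():
        hits = []
        for i in range(table.n_features):
            shift = ppm_shift(float(e.mz), table.mz[i])
            drt = abs(float(e.rt) - table.rt[i])
            if shift < ppm and drt < rt_tol:
                hits.append((str(table.ids[i]), shift, drt))
        if hits:
            for fid, shift, drt in hits:
                rows.append({"entry_id": str(e.id), "entry_mz": float(e.mz),
                             "entry_rt": float(e.rt), "feature_id": fid,
                             "ppm_shift": shift, "rt_shift": drt, "matched": True})
        else:
            rows.append({"entry_id": str(e.id), "entry_mz": float(e.mz),
                         "entry_rt": float(e.rt), "feature_id": pd.NA,
                         "ppm_shift": np.nan, "rt_shift": np.nan, "matched": False})
    return pd.DataFrame(
        rows,
        columns=["entry_id", "entry_mz", "entry_rt", "feature_id",
                 "ppm_shift", "rt_shift", "matched"],
    )


@dataclass(frozen=True)
class KnownCompound:
    """A reference compound with a known monoisotopic (neutral) mass."""

    name: str
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic mass must be positive")


def read_known_compounds(path) -> list[KnownCompound]:
    """Read a CSV of known compounds with name and monoisotopic_mass columns."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "name" not in cols or "monoisotopic_mass" not in cols:
        raise ValueError("known-compound table needs 'name' and 'monoisotopic_mass' columns")
    return [
        KnownCompound(str(r[cols["name"]]), float(r[cols["monoisotopic_mass"]]))
        for _, r in df.iterrows()
    ]


def _round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (deterministic).

    A 1e-7 guard absorbs binary float representation error at the .xx5
    boundary (1.005 is stored fractionally below its decimal value).
    """
    return float(np.sign(x) * np.floor(abs(x) * 100.0 + 0.5 + 1e-7) / 100.0)


def match_known_compounds(
    precursors: pd.DataFrame,
    compounds: list[KnownCompound],
    mode: str,
) -> pd.DataFrame:
    """Match precursor m/z against protonated/deprotonated theoretical ions.

    Theoretical m/z is mass + 1.00728 Da (positive mode, [M+H]+) or
    mass - 1.00728 Da (negative, [M-H]-); a precursor matches a compound
    when both m/z values agree after rounding to two decimal places. All
    matches are returned (a precursor can hit several isobaric compounds).
    """
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    sign = 1.0 if mode == "positive" else -1.0
    rows = []
    for comp in compounds:
        theo = comp.monoisotopic_mass + sign * PROTON_MASS
        theo_r = _round2(theo)
        for p in precursors.itertuples():
            if _round2(float(p.mz)) == theo_r:
                rows.append(
                    {
                        "compound": comp.name,
                        "monoisotopic_mass": comp.monoisotopic_mass,
                        "theoretical_mz": theo,
                        "precursor_id": str(p.id),
                        "precursor_mz": float(p.mz),
                        "mode": mode,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["compound", "monoisotopic_mass", "theoretical_mz",
                 "precursor_id", "precursor_mz", "mode"],
    )
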