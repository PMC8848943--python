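"""Feature-table, mzML and MGF input/output.

The MS1 substrate of the whole pipeline is a :class:`FeatureTable`: an
aligned peak list (one m/z – retention-time feature per row) with one
intensity column per sample, where each sample carries a role — ``study``
(the biological/reference replicates) or ``blank`` (matrix/extraction
blanks used only for background filtering).

Retention time is **seconds everywhere** inside the package; minutes are
converted at the I/O boundary (mzML scan start times declare their unit).
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

ROLE_STUDY = "study"
ROLE_BLANK = "blank"
_ROLES = (ROLE_STUDY, ROLE_BLANK)

#: auto-role prefixes used when no explicit role map is given
_BLANK_PREFIXES = ("blank", "matrix", "mb_", "mb-")


class FormatError(ValueError):
    """Raised when an input file does not follow the expected layout."""


@dataclass(frozen=True)
class SampleInfo:
    """A sample column of a feature table and its role."""

    name: str
    role: str = ROLE_STUDY

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown sample role {self.role!r}; expected one of {_ROLES}")


class FeatureTable:
    """Aligned MS1 feature matrix: (m/z, RT) rows x sample columns.

    Parameters
    ----------
    ids : sequence of str
        Unique opaque feature identifiers.
    mz : array-like
        Mass-to-charge ratio per feature, Da; strictly positive.
    rt : array-like
        Retention time per feature, seconds; non-negative.
    intensities : 2-D array-like
        Non-negative intensity matrix of shape (n_features, n_samples).
    samples : sequence of SampleInfo
        Column metadata, in column order.
    """

    def __init__(
        self,
        ids: Sequence[str],
        mz,
        rt,
        intensities,
        samples: Sequence[SampleInfo],
    ) -> None:
        self.ids = np.asarray(ids, dtype=object)
        self.mz = np.asarray(mz, dtype=float)
        self.rt = np.asarray(rt, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        self.samples = list(samples)
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.ids)
        if self.mz.shape != (n,) or self.rt.shape != (n,):
            raise ValueError("ids, mz and rt must have equal length")
        if self.intensities.shape != (n, len(self.samples)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"({n} features, {len(self.samples)} samples)"
            )
        if n and np.any(self.mz <= 0):
            raise ValueError("all feature m/z values must be > 0")
        if n and np.any(self.rt < 0):
            raise ValueError("all retention times must be >= 0")
        if n and np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if len(set(self.ids)) != n:
            raise ValueError("feature identifiers must be unique")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")

    # -- basic accessors --------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def role_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.role == role], dtype=int)

    @property
    def study_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_STUDY)

    @property
    def blank_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_BLANK)

    def study_intensities(self) -> np.ndarray:
        """Intensity sub-matrix of the study samples only."""
        return self.intensities[:, self.study_indices]

    def blank_intensities(self) -> np.ndarray:
        return self.intensities[:, self.blank_indices]

    def mean_study_intensity(self) -> np.ndarray:
        """Arithmetic mean intensity over study samples, per feature."""
        idx = self.study_indices
        if idx.size == 0:
            raise ValueError("table has no study samples")
        return self.intensities[:, idx].mean(axis=1)

    def index_of(self, feature_id: str) -> int:
        hits = np.nonzero(self.ids == feature_id)[0]
        if hits.size == 0:
            raise KeyError(feature_id)
        return int(hits[0])

    def subset(self, mask) -> "FeatureTable":
        """Row-subset (boolean mask or integer index array); samples unchanged."""
        mask = np.asarray(mask)
        return FeatureTable(
            self.ids[mask], self.mz[mask], self.rt[mask], self.intensities[mask], self.samples
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "mz": self.mz, "rt": self.rt})
        for j, s in enumerate(self.samples):
            df[s.name] = self.intensities[:, j]
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ns = sum(1 for s in self.samples if s.role == ROLE_STUDY)
        return (
            f"FeatureTable({self.n_features} features, {self.n_samples} samples "
            f"[{ns} study, {self.n_samples - ns} blank])"
        )


def _infer_role(name: str) -> str:
    low = name.lower()
    return ROLE_BLANK if any(low.startswith(p) for p in _BLANK_PREFIXES) else ROLE_STUDY


def read_feature_table(path, role_map: Mapping[str, str] | None = None) -> FeatureTable:
    """Read a comma-delimited feature table.

    Expected columns: optional ``id``, mandatory ``mz`` and ``rt``
    (seconds), then one numeric column per sample. ``role_map`` assigns
    ``study``/``blank`` roles by sample name; unnamed samples default to
    ``study``, except that names starting with "blank"/"matrix" are
    auto-assigned ``blank`` when no role map is given. Missing intensities
    are read as 0.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    cols = {c.lower(): c for c in df.columns}
    if "mz" not in cols or "rt" not in cols:
        raise FormatError(f"{path}: feature table must contain 'mz' and 'rt' columns")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no features (header only)")
    id_col = cols.get("id")
    ids = (
        df[id_col].astype(str).to_numpy()
        if id_col is not None
        else np.array([f"F{i + 1:05d}" for i in range(len(df))], dtype=object)
    )
    sample_cols = [c for c in df.columns if c not in {cols["mz"], cols["rt"], id_col}]
    if not sample_cols:
        raise FormatError(f"{path}: no sample intensity columns found")
    inten = df[sample_cols].fillna(0.0)
    try:
        inten = inten.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric intensity value: {exc}") from exc
    samples = [
        SampleInfo(c, role_map.get(c, ROLE_STUDY) if role_map is not None else _infer_role(c))
        for c in sample_cols
    ]
    return FeatureTable(ids, df[cols["mz"]].astype(float), df[cols["rt"]].astype(float),
                        inten.to_numpy(), samples)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV with columns id, mz, rt, samples (input order)."""
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MS2 scans
# ---------------------------------------------------------------------------

@dataclass
class MS2Scan:
    """One centroided fragment spectrum with its precursor context.

    Fragments are normalised to ascending m/z order on construction.
    """

    precursor_mz: float
    rt: float  # seconds
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    source_run: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("fragment m/z and intensity arrays must have equal length")
        if np.any(self.mz <= 0):
            raise ValueError("fragment m/z must be strictly positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def fragments(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def n_fragments(self) -> int:
        return int(self.mz.size)


# PSI-MS controlled-vocabulary accessions used by the mzML parser
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_SELECTED_MZ = "MS:1000744"
_CV_ISOLATION_MZ = "MS:1000827"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cvparams(elem) -> dict[str, dict]:
    out = {}
    for child in elem:
        if _localname(child.tag) == "cvParam":
            out[child.get("accession", child.get("name", ""))] = dict(child.attrib)
    return out


def _iter_local(elem, name: str):
    for child in elem.iter():
        if _localname(child.tag) == name:
            yield child


def _decode_binary_array(bda) -> np.ndarray:
    params = _cvparams(bda)
    text = ""
    for child in _iter_local(bda, "binary"):
        text = child.text or ""
    raw = base64.b64decode(text) if text else b""
    if _CV_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV_F32 in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(spec, source_run: str) -> MS2Scan | None:
    """Build an MS2Scan from one <spectrum> element; None for non-MS2."""
    params = _cvparams(spec)
    level = params.get(_CV_MS_LEVEL, {}).get("value")
    if level is None or int(level) != 2:
        return None

    rt_s = None
    for scan_el in _iter_local(spec, "scan"):
        sp = _cvparams(scan_el)
        if _CV_SCAN_START in sp:
            attrs = sp[_CV_SCAN_START]
            rt_s = float(attrs["value"])
            if attrs.get("unitName", "").startswith("minute"):
                rt_s *= 60.0
        break
    if rt_s is None:
        raise FormatError("MS2 spectrum without a scan start time")

    precursor_mz = None
    for ion in _iter_local(spec, "selectedIon"):
        ip = _cvparams(ion)
        for acc in (_CV_SELECTED_MZ, _CV_ISOLATION_MZ):
            if acc in ip:
                precursor_mz = float(ip[acc]["value"])
        break
    if precursor_mz is None:
        raise FormatError("MS2 spectrum without a selected-ion m/z")

    mz = intensity = None
    for bda in _iter_local(spec, "binaryDataArray"):
        p = _cvparams(bda)
        if _CV_MZ_ARRAY in p:
            mz = _decode_binary_array(bda)
        elif _CV_INT_ARRAY in p:
            intensity = _decode_binary_array(bda)
    if mz is None or intensity is None:
        raise FormatError("MS2 spectrum without m/z or intensity arrays")
    return MS2Scan(precursor_mz, rt_s, mz, intensity, source_run)


def read_ms2_runs(paths: Iterable) -> list[MS2Scan]:
    """Read MS-level-2 scans from one or more centroided mzML files.

    Uses a self-contained PSI-mzML parser (stdlib XML + base64/zlib
    binary decoding of 32/64-bit float arrays). RT is converted to
    seconds when the scan start time is declared in minutes; MS1 scans
    are skipped. A file without MS2 scans yields a warning, not an error.
    """
    import xml.etree.ElementTree as ET

    scans: list[MS2Scan] = []
    for path in paths:
        path = Path(path)
        n_before = len(scans)
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise FormatError(f"{path}: cannot parse mzML: {exc}") from exc
        if _localname(root.tag) not in ("mzML", "indexedmzML"):
            raise FormatError(f"{path}: root element {root.tag!r} is not mzML")
        for spec in _iter_local(root, "spectrum"):
            scan = _parse_mzml_spectrum(spec, path.stem)
            if scan is not None:
                scans.append(scan)
        if len(scans) == n_before:
            warnings.warn(f"{path}: no MS2 scans found", stacklevel=2)
    return scans


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_mzml(scans: Sequence[MS2Scan], path, rt_unit: str = "second") -> None:
    """Write centroided MS2 scans as a minimal PSI mzML document.

    Exists so synthetic fragment runs can be exercised through the real
    mzML reading path; emits 64-bit little-endian zlib-compressed arrays.
    """
    if rt_unit not in ("second", "minute"):
        raise ValueError("rt_unit must be 'second' or 'minute'")
    unit_acc = "UO:0000010" if rt_unit == "second" else "UO:0000031"
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <run id="%s">' % escape(Path(path).stem),
        '    <spectrumList count="%d">' % len(scans),
    ]
    for i, scan in enumerate(scans):
        rt_val = scan.rt / 60.0 if rt_unit == "minute" else scan.rt
        mz_b64 = _encode_array(scan.mz)
        it_b64 = _encode_array(scan.intensity)
        lines += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.n_fragments}">',
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>',
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            '        <scanList count="1">',
            '          <scan>',
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt_val!r}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{rt_unit}"/>',
            '          </scan>',
            '        </scanList>',
            '        <precursorList count="1">',
            '          <precursor>',
            '            <selectedIonList count="1">',
            '              <selectedIon>',
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{scan.precursor_mz!r}"/>',
            '              </selectedIon>',
            '            </selectedIonList>',
            '          </precursor>',
            '        </precursorList>',
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>',
            f'            <binary>{mz_b64}</binary>',
            '          </binaryDataArray>',
            f'          <binaryDataArray encodedLength="{len(it_b64)}">',
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>',
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>',
            f'            <binary>{it_b64}</binary>',
            '          </binaryDataArray>',
            '        </binaryDataArrayList>',
            '      </spectrum>',
        ]
    lines += ['    </spectrumList>', '  </run>', '</mzML>', '']
    Path(path).write_text("\n".join(lines))


def write_mgf(spectra, path) -> None:
    """Write consensus spectra to MGF.

    Each block carries PEPMASS, RTINSECONDS and TITLE=<target feature id>;
    fragment lines are ascending in m/z. Spectra without fragments are
    skipped with a warning.
    """
    path = Path(path)
    blocks: list[str] = []
    for spec in spectra:
        mz = np.asarray(spec.mz, dtype=float)
        inten = np.asarray(spec.intensity, dtype=float)
        if mz.size == 0:
            warnings.warn(f"spectrum {spec.target_feature!r} has no fragments; skipped",
                          stacklevel=2)
            continue
        order = np.argsort(mz, kind="stable")
        lines = [
            "BEGIN IONS",
            f"TITLE={spec.target_feature}",
            f"PEPMASS={spec.precursor_mz:.5f}",
            f"RTINSECONDS={spec.rt:.3f}",
        ]
        lines += [f"{m:.5f} {i:.4f}" for m, i in zip(mz[order], inten[order])]
        lines.append("END IONS")
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + ("\n" if blocks else ""))
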