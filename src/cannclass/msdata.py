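"""Mass-spectral data handling: MSP I/O, normalization, cropping, unit-mass binning.

Spectra are low-resolution (nominal mass) electron-ionization spectra. The
working representation for chemometrics is a samples x m/z intensity matrix on
an integer m/z axis, by default 40..300 (261 variables), with intensities
expressed relative to the base peak (most intense peak = 100).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: allowed values of :attr:`ClassAnnotation.core_group`
CORE_GROUPS = ("indole", "indazole", "azaindole", "naphthoylpyrrole", "other", "n/a")

DEFAULT_MZ_LO = 40
DEFAULT_MZ_HI = 300


def _canonical_peaks(peaks):
    """Sort peaks by m/z and sum intensities of exactly coincident m/z values."""
    merged: dict[float, float] = {}
    for mz, inten in peaks:
        mz = float(mz)
        merged[mz] = merged.get(mz, 0.0) + float(inten)
    return tuple(sorted(merged.items()))


@dataclass(frozen=True)
class MassSpectrum:
    """One compound's EI mass spectrum as a list of (m/z, intensity) peaks.

    Peaks are canonicalized on construction: sorted by m/z, exact-duplicate
    m/z values merged by summing. Intensities are arbitrary non-negative
    abundances until :func:`normalize_base_peak` puts them on the relative
    (base peak = 100) scale.
    """

    compound_id: str
    name: str
    peaks: tuple[tuple[float, float], ...]
    source: str = ""

    def __post_init__(self):
        if len(self.peaks) == 0:
            raise ValueError(f"spectrum {self.compound_id!r}: empty peak list")
        object.__setattr__(self, "peaks", _canonical_peaks(self.peaks))
        mzs = np.array([p[0] for p in self.peaks])
        ints = np.array([p[1] for p in self.peaks])
        if np.any(mzs <= 0):
            raise ValueError(f"spectrum {self.compound_id!r}: non-positive m/z")
        if np.any(ints < 0):
            raise ValueError(f"spectrum {self.compound_id!r}: negative intensity")
        if not np.any(ints > 0):
            raise ValueError(f"spectrum {self.compound_id!r}: all intensities zero")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


@dataclass(frozen=True)
class ClassAnnotation:
    """Ground-truth labels of one compound at every node of the decision cascade.

    ``None`` encodes "unknown / not applicable" explicitly; subgroup labels are
    only meaningful on the branch of the cascade that reaches them (core, head
    and tail groups exist only for non-classical, i.e. synthetic, cannabinoids).
    """

    compound_id: str
    is_cannabinoid: bool
    is_classical: bool | None = None
    core_group: str = "n/a"
    head_is_naphthyl: bool | None = None
    tail_is_fub: bool | None = None
    tail_is_5f_pentyl: bool | None = None

    def __post_init__(self):
        if self.core_group not in CORE_GROUPS:
            raise ValueError(
                f"{self.compound_id!r}: core_group {self.core_group!r} "
                f"not one of {CORE_GROUPS}"
            )
        if not self.is_cannabinoid:
            if self.is_classical is not None or self.core_group != "n/a" or any(
                v is not None
                for v in (self.head_is_naphthyl, self.tail_is_fub, self.tail_is_5f_pentyl)
            ):
                raise ValueError(
                    f"{self.compound_id!r}: subgroup labels set on a non-cannabinoid"
                )
        elif self.is_classical:
            if self.core_group != "n/a" or any(
                v is not None
                for v in (self.head_is_naphthyl, self.tail_is_fub, self.tail_is_5f_pentyl)
            ):
                raise ValueError(
                    f"{self.compound_id!r}: core/head/tail labels set on a "
                    "classical cannabinoid"
                )


@dataclass
class SpectrumMatrix:
    """Samples x unit-mass intensity matrix with aligned ids and annotations."""

    X: np.ndarray
    mz_axis: np.ndarray
    sample_ids: list[str]
    annotations: list[ClassAnnotation]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis)
        n, p = self.X.shape
        if len(self.mz_axis) != p:
            raise ValueError("mz_axis length does not match matrix columns")
        if len(self.sample_ids) != n or len(self.annotations) != n:
            raise ValueError("sample_ids/annotations length does not match rows")
        if np.any(self.X < 0):
            raise ValueError("negative intensities in spectrum matrix")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# MSP I/O (NIST-style text records)
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^\s*name\s*:\s*(.*)$", re.IGNORECASE)
_NUMPEAKS_RE = re.compile(r"^\s*num\s*peaks\s*:\s*(\d+)\s*$", re.IGNORECASE)
_FIELD_RE = re.compile(r"^\s*[A-Za-z][A-Za-z0-9_#\s/.-]*:\s*")


def read_msp(path, source: str = "") -> list[MassSpectrum]:
    """Read a NIST-style MSP library file.

    Records are separated by blank lines and carry at least ``Name:`` and
    ``Num Peaks:`` headers followed by whitespace- or semicolon-separated
    m/z-intensity pairs (one or several pairs per line). Other ``Key: value``
    header lines are ignored. A record whose parsed peak count differs from
    its declared ``Num Peaks`` is rejected with a logged warning; the rest of
    the file is still read. An MSP file with no valid record is an error.
    """
    with open(path) as fh:
        text = fh.read()
    blocks = re.split(r"\n\s*\n", text)
    spectra: list[MassSpectrum] = []
    n_declared = 0
    for block in blocks:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        name = None
        num_peaks = None
        tokens: list[str] = []
        for ln in lines:
            m = _NAME_RE.match(ln)
            if m and name is None:
                name = m.group(1).strip()
                continue
            m = _NUMPEAKS_RE.match(ln)
            if m:
                num_peaks = int(m.group(1))
                continue
            if num_peaks is None:
                # header/comment line before the peak table: ignored
                continue
            tokens.extend(ln.replace(";", " ").replace(",", " ").split())
        if num_peaks is None:
            if name is not None:
                logger.warning("MSP record %r has no 'Num Peaks' header; skipped", name)
            continue
        n_declared += 1
        label = name if name is not None else f"record_{n_declared}"
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            logger.warning("MSP record %r has non-numeric peak data; skipped", label)
            continue
        if len(values) != 2 * num_peaks:
            logger.warning(
                "MSP record %r declares %d peaks but lists %s; skipped",
                label, num_peaks, f"{len(values) / 2:g}",
            )
            continue
        peaks = list(zip(values[0::2], values[1::2]))
        try:
            spectra.append(
                MassSpectrum(compound_id=label, name=label, peaks=tuple(peaks),
                             source=source)
            )
        except ValueError as exc:
            logger.warning("MSP record %r invalid (%s); skipped", label, exc)
    if not spectra:
        raise ValueError(f"no valid MSP records in {path}")
    return spectra


def write_msp(spectra: list[MassSpectrum], path) -> None:
    """Write spectra as NIST-style MSP text (one m/z-intensity pair per line)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"Name: {s.name}\n")
            if s.source:
                fh.write(f"Comments: source={s.source}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.10g} {inten:.10g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Spectrum transforms
# ---------------------------------------------------------------------------

def normalize_base_peak(s: MassSpectrum, scale: float = 100.0) -> MassSpectrum:
    """Rescale intensities so the base (most intense) peak equals ``scale``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    top = max(p[1] for p in s.peaks)
    if top <= 0:
        raise ValueError(f"spectrum {s.compound_id!r}: no positive intensity")
    factor = scale / top
    return replace(s, peaks=tuple((mz, i * factor) for mz, i in s.peaks))


def crop_spectrum(s: MassSpectrum, lo: int = DEFAULT_MZ_LO,
                  hi: int = DEFAULT_MZ_HI) -> MassSpectrum | None:
    """Retain peaks whose nominal mass round(m/z) lies in [lo, hi] inclusive.

    Returns ``None`` when no peak survives (the matrix builder treats that as
    an error naming the compound).
    """
    if lo >= hi:
        raise ValueError("crop bounds require lo < hi")
    kept = tuple(
        (mz, i) for mz, i in s.peaks if lo <= _round_half_up(mz) <= hi
    )
    if not kept:
        return None
    return replace(s, peaks=kept)


def _round_half_up(x: float) -> int:
    # np.round / round() round half to even; nominal-mass assignment uses
    # the conventional round-half-up
    return int(np.floor(x + 0.5))


def bin_to_unit_mass(s: MassSpectrum, lo: int = DEFAULT_MZ_LO,
                     hi: int = DEFAULT_MZ_HI) -> np.ndarray:
    """Vectorize a cropped spectrum on the integer m/z axis lo..hi.

    Each peak goes to bin ``round(mz) - lo`` (round half up); peaks rounding
    to the same nominal mass are summed.
    """
    vec = np.zeros(hi - lo + 1)
    for mz, inten in s.peaks:
        idx = _round_half_up(mz) - lo
        if 0 <= idx <= hi - lo:
            vec[idx] += inten
    return vec


def build_matrix(
    spectra: list[MassSpectrum],
    annotations: list[ClassAnnotation],
    lo: int = DEFAULT_MZ_LO,
    hi: int = DEFAULT_MZ_HI,
    scale: float = 100.0,
) -> SpectrumMatrix:
    """Normalize, crop and bin spectra into a labeled SpectrumMatrix.

    Base-peak normalization happens before cropping so the base peak is
    defined on the full spectrum. Row order equals input order. Every
    spectrum must have exactly one annotation with a matching compound_id.
    """
    ann_by_id: dict[str, ClassAnnotation] = {}
    for ann in annotations:
        if ann.compound_id in ann_by_id:
            raise ValueError(f"duplicate annotation for compound {ann.compound_id!r}")
        ann_by_id[ann.compound_id] = ann
    seen: set[str] = set()
    rows, ids, anns = [], [], []
    for s in spectra:
        if s.compound_id in seen:
            raise ValueError(f"duplicate compound id {s.compound_id!r} in spectra")
        seen.add(s.compound_id)
        if s.compound_id not in ann_by_id:
            raise ValueError(f"no annotation for compound {s.compound_id!r}")
        cropped = crop_spectrum(normalize_base_peak(s, scale), lo, hi)
        if cropped is None:
            raise ValueError(
                f"compound {s.compound_id!r} has no peaks in m/z [{lo}, {hi}]"
            )
        rows.append(bin_to_unit_mass(cropped, lo, hi))
        ids.append(s.compound_id)
        anns.append(ann_by_id[s.compound_id])
    if not rows:
        raise ValueError("no spectra supplied")
    return SpectrumMatrix(
        X=np.vstack(rows),
        mz_axis=np.arange(lo, hi + 1),
        sample_ids=ids,
        annotations=anns,
    )


# ---------------------------------------------------------------------------
# Annotation table I/O (CSV)
# ---------------------------------------------------------------------------

_ANN_COLUMNS = [
    "compound_id", "is_cannabinoid", "is_classical", "core_group",
    "head_is_naphthyl", "tail_is_fub", "tail_is_5f_pentyl",
]

_BOOL_MAP = {"true": True, "1": True, "yes": True,
             "false": False, "0": False, "no": False}


def _parse_optional_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip().lower()
    if s in ("", "na", "n/a", "none"):
        return None
    if s in _BOOL_MAP:
        return _BOOL_MAP[s]
    raise ValueError(f"cannot parse boolean value {v!r}")


def read_annotations(path) -> list[ClassAnnotation]:
    """Read a ClassAnnotation table from CSV (columns as written by
    :func:`write_annotations`; empty cells mean unknown/not-applicable)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        is_cann = _parse_optional_bool(row["is_cannabinoid"])
        if is_cann is None:
            raise ValueError(
                f"compound {row['compound_id']!r}: is_cannabinoid must be set"
            )
        core = str(row["core_group"]).strip() or "n/a"
        out.append(ClassAnnotation(
            compound_id=str(row["compound_id"]),
            is_cannabinoid=is_cann,
            is_classical=_parse_optional_bool(row["is_classical"]),
            core_group=core,
            head_is_naphthyl=_parse_optional_bool(row["head_is_naphthyl"]),
            tail_is_fub=_parse_optional_bool(row["tail_is_fub"]),
            tail_is_5f_pentyl=_parse_optional_bool(row["tail_is_5f_pentyl"]),
        ))
    return out


def write_annotations(annotations: list[ClassAnnotation], path) -> None:
    def enc(v):
        return "" if v is None else ("true" if v else "false")

    df = pd.DataFrame(
        {
            "compound_id": [a.compound_id for a in annotations],
            "is_cannabinoid": [enc(a.is_cannabinoid) for a in annotations],
            "is_classical": [enc(a.is_classical) for a in annotations],
            "core_group": [a.core_group for a in annotations],
            "head_is_naphthyl": [enc(a.head_is_naphthyl) for a in annotations],
            "tail_is_fub": [enc(a.tail_is_fub) for a in annotations],
            "tail_is_5f_pentyl": [enc(a.tail_is_5f_pentyl) for a in annotations],
        }
    )
    df.to_csv(path, index=False)
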