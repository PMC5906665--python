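"""Spectrum containers, MGF/MSP I/O, the packaged metabolite fixture, and the
signal-library filter (s/n and VIP thresholds plus precursor/RT deduplication).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "FixtureRecord",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "write_msp",
    "load_table1_fixture",
    "classify_record",
    "build_signal_library",
    "PROTEINOGENIC_AMINO_ACIDS",
]

#: The 20 proteinogenic amino acids, for record classification.
PROTEINOGENIC_AMINO_ACIDS = frozenset(
    {
        "alanine", "arginine", "asparagine", "aspartic acid", "cysteine",
        "glutamic acid", "glutamine", "glycine", "histidine", "isoleucine",
        "leucine", "lysine", "methionine", "phenylalanine", "proline",
        "serine", "threonine", "tryptophan", "tyrosine", "valine",
    }
)

#: Name tokens that mark a glycosyl/acyl modification in the field's
#: compound-naming grammar.
GLYCO_GRAMMAR_TOKENS = (
    "hexoside", "glucoside", "pentoside", "hexosyl", "pentosyl",
    "glucosyl", "deoxyhexosyl", "rhamnosyl", "malonyl", "feruloyl",
    "coumaroyl", "o-", "c-",
)

# SHA-256 of the packaged fixture TSV; the fixture is the annotation
# acceptance surface and must not drift.
_FIXTURE_SHA256 = "59e2c79daaa5a26076243287671f3070e0f5891628e28402a6f9d06fc6a797ce"


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A product-ion spectrum: precursor plus an m/z-sorted fragment list."""

    id: str
    precursor_mz: float
    rt_min: float = 0.0
    polarity: str = "+"
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    snr: float | None = None
    vip: float | None = None

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError(f"retention time must be non-negative, got {self.rt_min}")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)

    @property
    def fragment_mzs(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    def has_superprecursor_peaks(self) -> bool:
        """Fragments above the precursor m/z (isotope/coelution artifacts);
        allowed, but worth flagging."""
        return any(p.mz > self.precursor_mz for p in self.peaks)


@dataclass(frozen=True)
class FixtureRecord:
    """One row of the packaged metabolite table (name, RT, precursor,
    main fragments as printed)."""

    name: str
    rt_min: float
    precursor_mz: float
    fragments: tuple[float, ...]
    record_class: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("fixture record needs a non-empty name")

    def to_spectrum(self) -> Spectrum:
        return Spectrum(
            id=self.name,
            precursor_mz=self.precursor_mz,
            rt_min=self.rt_min,
            peaks=tuple(Peak(mz) for mz in self.fragments),
        )


# -- MGF ---------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file (BEGIN IONS / END IONS blocks) into spectra.

    RTINSECONDS is converted to minutes (RTINMINUTES taken as-is); peaks come
    out sorted by m/z. A block without PEPMASS is an error.
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise ValueError(f"{path}: spectrum block {i + 1} has no PEPMASS")
                precursor = float(params["pepmass"][0])
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"]) / 60.0
                elif "rtinminutes" in params:
                    rt = float(params["rtinminutes"])
                else:
                    rt = 0.0
                sid = str(params.get("title", f"spectrum_{i + 1}"))
                snr = float(params["snr"]) if "snr" in params else None
                vip = float(params["vip"]) if "vip" in params else None
                peaks = tuple(
                    Peak(float(mz), float(inten))
                    for mz, inten in zip(entry["m/z array"], entry["intensity array"])
                )
                spectra.append(
                    Spectrum(id=sid, precursor_mz=precursor, rt_min=rt, peaks=peaks,
                             snr=snr, vip=vip)
                )
    except ValueError:
        raise
    except Exception as exc:  # pyteomics raises format-specific errors
        raise ValueError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; s/n and VIP round-trip via SNR=/VIP= headers."""
    records = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz, "rtinseconds": s.rt_min * 60.0}
        if s.snr is not None:
            params["snr"] = s.snr
        if s.vip is not None:
            params["vip"] = s.vip
        records.append(
            {
                "params": params,
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
            }
        )
    _mgf.write(records, str(path), file_mode="w")


# -- MSP ---------------------------------------------------------------------


def read_msp(path: str | Path) -> list[Spectrum]:
    """Read NIST-style MSP text records (Name / PrecursorMZ / Num Peaks).

    The listed peak count must equal the ``Num Peaks`` header exactly.
    """
    spectra: list[Spectrum] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.lower().startswith("name:"):
            raise ValueError(f"{path}:{i + 1}: expected 'Name:' record start, got {line!r}")
        meta: dict[str, str] = {}
        while i < len(lines) and lines[i].strip() and ":" in lines[i]:
            key, _, value = lines[i].partition(":")
            key = key.strip().lower().replace(" ", "")
            meta[key] = value.strip()
            i += 1
            if key == "numpeaks":
                break
        if "numpeaks" not in meta:
            raise ValueError(f"{path}: record {meta.get('name', '?')!r} has no 'Num Peaks'")
        n_peaks = int(meta["numpeaks"])
        peaks = []
        while i < len(lines) and lines[i].strip() and ":" not in lines[i]:
            for pair in lines[i].replace(";", " ").split():
                peaks.append(pair)
            i += 1
        if len(peaks) % 2 != 0:
            raise ValueError(f"{path}: odd number of peak values in record {meta['name']!r}")
        peak_objs = tuple(
            Peak(float(peaks[j]), float(peaks[j + 1])) for j in range(0, len(peaks), 2)
        )
        if len(peak_objs) != n_peaks:
            raise ValueError(
                f"{path}: record {meta['name']!r} declares {n_peaks} peaks but lists {len(peak_objs)}"
            )
        if "precursormz" not in meta:
            raise ValueError(f"{path}: record {meta['name']!r} has no PrecursorMZ")
        rt = float(meta.get("retentiontime", meta.get("rt", 0.0)))
        spectra.append(
            Spectrum(
                id=meta["name"],
                precursor_mz=float(meta["precursormz"]),
                rt_min=rt,
                peaks=peak_objs,
                snr=float(meta["snr"]) if "snr" in meta else None,
                vip=float(meta["vip"]) if "vip" in meta else None,
            )
        )
    return spectra


def write_msp(spectra: Iterable[Spectrum], path: str | Path) -> None:
    out = []
    for s in spectra:
        out.append(f"Name: {s.id}")
        out.append(f"PrecursorMZ: {s.precursor_mz:.4f}")
        out.append(f"RetentionTime: {s.rt_min:.4f}")
        if s.snr is not None:
            out.append(f"SNR: {s.snr:.4f}")
        if s.vip is not None:
            out.append(f"VIP: {s.vip:.4f}")
        out.append(f"Num Peaks: {len(s.peaks)}")
        for p in s.peaks:
            out.append(f"{p.mz:.4f} {p.intensity:.6f}")
        out.append("")
    Path(path).write_text("\n".join(out))


# -- packaged fixture --------------------------------------------------------


def _fixture_path() -> Path:
    return Path(str(resources.files("glycoflav").joinpath("data/table1_metabolites.tsv")))


def load_table1_fixture(path: str | Path | None = None, classify: bool = True) -> list[FixtureRecord]:
    """Load the packaged 54-metabolite table (leaf metabolites with RT,
    precursor m/z and printed main fragments).

    The packaged copy is checksum-guarded; a record count other than 54 means
    the fixture is corrupted.
    """
    p = _fixture_path() if path is None else Path(path)
    raw = p.read_bytes()
    if path is None:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError(f"packaged fixture checksum mismatch: {digest}")
    lines = raw.decode().splitlines()
    if lines[0] != "name\trt_min\tmz\tfragments":
        raise ValueError(f"{p}: unexpected fixture header {lines[0]!r}")
    records = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        name, rt, mz, frags = ln.split("\t")
        fragments = tuple(float(x) for x in frags.split(",")) if frags.strip() else ()
        records.append(FixtureRecord(name, float(rt), float(mz), fragments))
    if len(records) != 54:
        raise ValueError(f"{p}: fixture corrupted, {len(records)} records instead of 54")
    if classify:
        from .annotate import default_aglycone_names

        aglycones = default_aglycone_names()
        records = [
            replace(r, record_class=classify_record(r, PROTEINOGENIC_AMINO_ACIDS, aglycones))
            for r in records
        ]
    return records


def classify_record(
    rec: FixtureRecord, aa_names: frozenset[str] | set[str], aglycone_names: set[str] | frozenset[str]
) -> str:
    """Partition a metabolite record into amino-acid / flavonoid / other.

    Amino acid: name is one of the 20 proteinogenic amino acids.  Flavonoid:
    the name carries an aglycone token or glycosyl/acyl grammar token, or is a
    bare aglycone.  Everything else (here: oxidized glutathione, a peptide) is
    'other'.
    """
    if not aa_names or not aglycone_names:
        raise ValueError("classification dictionaries must be non-empty")
    name = rec.name.lower()
    if name in {a.lower() for a in aa_names}:
        return "amino-acid"
    if any(agl.lower() in name for agl in aglycone_names):
        return "flavonoid"
    if any(tok in name for tok in GLYCO_GRAMMAR_TOKENS):
        return "flavonoid"
    return "other"


# -- signal library ----------------------------------------------------------


def build_signal_library(
    spectra: Sequence[Spectrum],
    snr_min: float = 10.0,
    vip_min: float = 1.0,
    rt_tol: float = 0.1,
    mz_tol: float = 0.01,
) -> list[Spectrum]:
    """Quality-filter and deduplicate signals into an annotation library.

    A spectrum is retained iff ``snr > snr_min`` and ``vip > vip_min`` (a
    missing value fails that filter).  Survivors are greedily clustered in
    descending s/n order (ties: lexicographically lower id first): a spectrum
    joins an existing representative when both its precursor m/z (within
    *mz_tol* Da) and RT (within *rt_tol* min) agree; otherwise it becomes a
    new representative.  The library is returned sorted by RT.
    """
    kept = []
    for s in spectra:
        if s.snr is None or s.vip is None:
            logger.info("signal %s dropped: missing s/n or VIP", s.id)
            continue
        if s.snr > snr_min and s.vip > vip_min:
            kept.append(s)
    kept.sort(key=lambda s: (-s.snr, s.id))
    representatives: list[Spectrum] = []
    for s in kept:
        is_dup = any(
            abs(s.precursor_mz - r.precursor_mz) <= mz_tol and abs(s.rt_min - r.rt_min) <= rt_tol
            for r in representatives
        )
        if not is_dup:
            representatives.append(s)
    representatives.sort(key=lambda s: (s.rt_min, s.id))
    return representatives
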