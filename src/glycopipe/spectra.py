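"""MGF spectrum I/O, deisotoping, oxonium handling and HCD/CID pairing.

Spectra come from product-dependent acquisition: an HCD scan (NCE 40%)
whose oxonium ions (the 138.055 trigger) fire either a CID scan of the
same precursor (run 1) or an MS3 scan of an intense MS2 fragment, the Y1
ion (run 2).  The spectrum ``kind`` (HCD2 / CID2 / MS3) is carried in the
MGF TITLE as a ``kind=...`` tag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pt_mgf

from .masses import neutral_from_mz

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumPair",
    "OXONIUM_MZ",
    "NEUTRON",
    "read_mgf",
    "write_mgf",
    "deisotope",
    "strip_oxonium",
    "pair_spectra",
]

#: C13-C12 spacing used for isotope-cluster detection.
NEUTRON = 1.00335

#: Default glyco-oxonium m/z list: HexNAc series (126.055, 138.055 trigger,
#: 144.066, 168.066, 186.076, 204.087), Hex 163.060, NeuAc 274.092/292.103,
#: HexHexNAc 366.140, NeuAcHexHexNAc 657.235.
OXONIUM_MZ: tuple[float, ...] = (
    126.0550,
    138.0550,
    144.0655,
    163.0601,
    168.0655,
    186.0761,
    204.0867,
    274.0921,
    292.1027,
    366.1395,
    657.2349,
)

TRIGGER_ION_MZ = 138.0550


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    charge: int = 0  # 0 = unassigned; set by deisotoping

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    title: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float  # seconds
    peaks: list[Peak]
    kind: str = "HCD2"  # HCD2 | CID2 | MS3

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.retention_time < 0:
            raise ValueError("retention time must be >= 0")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def precursor_neutral(self) -> float:
        return neutral_from_mz(self.precursor_mz, self.precursor_charge)

    @property
    def mz_array(self) -> np.ndarray:
        return np.asarray([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.asarray([p.intensity for p in self.peaks])

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


@dataclass
class SpectrumPair:
    """An HCD spectrum and its product-dependent CID sister."""

    hcd: Spectrum
    cid: Spectrum
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.pair_id:
            self.pair_id = self.hcd.title
        if self.hcd.precursor_charge != self.cid.precursor_charge:
            raise ValueError("paired spectra must share the precursor charge")

    @property
    def precursor_neutral(self) -> float:
        return self.hcd.precursor_neutral

    @property
    def precursor_charge(self) -> int:
        return self.hcd.precursor_charge

    @property
    def retention_time(self) -> float:
        return self.hcd.retention_time


# ---------------------------------------------------------------------------
# MGF reading / writing (pyteomics behind the surface)
# ---------------------------------------------------------------------------

def _kind_from_title(title: str, default: str | None) -> str:
    for token in title.replace(";", " ").split():
        if token.lower().startswith("kind="):
            kind = token.split("=", 1)[1].upper()
            if kind not in {"HCD2", "CID2", "MS3"}:
                raise ValueError(f"unknown spectrum kind {kind!r} in title {title!r}")
            return kind
    if default is None:
        raise ValueError(f"no kind=... tag in title {title!r} and no default kind")
    return default


def read_mgf(
    path: str | Path,
    default_kind: str | None = "HCD2",
    default_charge: int | None = None,
) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    TITLE, PEPMASS (first field = precursor m/z), CHARGE ("2+" form) and
    RTINSECONDS are honoured; a missing RTINSECONDS defaults to 0 with a
    warning, a missing CHARGE uses ``default_charge`` or is rejected.
    """
    spectra: list[Spectrum] = []
    with _pt_mgf.MGF(str(path), convert_arrays=1) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"scan_{len(spectra) + 1}"))
            if "charge" in params:
                charge = int(params["charge"][0])
            elif default_charge is not None:
                charge = default_charge
            else:
                raise ValueError(f"spectrum {title!r} has no CHARGE and no default")
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"])
            else:
                warnings.warn(f"spectrum {title!r} has no RTINSECONDS; using 0")
                rt = 0.0
            peaks = [
                Peak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            ]
            spectra.append(
                Spectrum(
                    title=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    retention_time=rt,
                    peaks=peaks,
                    kind=_kind_from_title(title, default_kind),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF, embedding the kind tag in each TITLE."""
    entries = []
    for s in spectra:
        title = s.title if "kind=" in s.title else f"{s.title} kind={s.kind}"
        entries.append(
            {
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
                "params": {
                    "title": title,
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                    "rtinseconds": s.retention_time,
                },
            }
        )
    _pt_mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Peak-list processing
# ---------------------------------------------------------------------------

def deisotope(s: Spectrum, max_charge: int | None = None, tol_ppm: float = 20.0) -> Spectrum:
    """Collapse isotope clusters to monoisotopic peaks.

    Greedy, intensity-descending: the most intense unclaimed peak seeds a
    cluster; for each charge z from ``max_charge`` down to 1 the ladder
    mz + k·1.00335/z is followed while peaks fall within ``tol_ppm``; the
    longest ladder wins.  No isotope-pattern fit is attempted.  The cluster
    is then also extended downward one step to catch a seed that is the
    A+1 peak.  Each cluster becomes one peak at the monoisotopic m/z with
    summed intensity and the assigned charge.
    """
    if max_charge is None:
        max_charge = max(1, s.precursor_charge)
    n = len(s.peaks)
    if n == 0:
        return replace(s, peaks=[])
    mzs = s.mz_array
    intens = s.intensity_array
    claimed = np.zeros(n, dtype=bool)
    out: list[Peak] = []

    def find(mz_target: float, tol_da: float) -> int:
        i = int(np.searchsorted(mzs, mz_target))
        best, best_d = -1, tol_da
        for j in (i - 1, i):
            if 0 <= j < n and not claimed[j]:
                d = abs(mzs[j] - mz_target)
                if d <= best_d:
                    best, best_d = j, d
        return best

    for idx in np.argsort(-intens):
        if claimed[idx]:
            continue
        seed_mz = mzs[idx]
        tol_da = seed_mz * tol_ppm * 1e-6
        best_ladder: list[int] = [int(idx)]
        best_z = 0
        for z in range(max_charge, 0, -1):
            step = NEUTRON / z
            ladder = [int(idx)]
            claimed[idx] = True  # temporarily, so find() skips the seed
            m = seed_mz
            while True:
                j = find(m + step, tol_da)
                if j < 0:
                    break
                ladder.append(j)
                claimed[j] = True
                m = mzs[j]
            # also look one step below the seed (seed may be A+1)
            j = find(seed_mz - step, tol_da)
            if j >= 0:
                ladder.insert(0, j)
                claimed[j] = True
            for j in ladder:
                claimed[j] = False
            if len(ladder) > len(best_ladder):
                best_ladder, best_z = ladder, z
        for j in best_ladder:
            claimed[j] = True
        mono = min(best_ladder, key=lambda j: mzs[j])
        out.append(
            Peak(
                mz=float(mzs[mono]),
                intensity=float(sum(intens[j] for j in best_ladder)),
                charge=best_z if len(best_ladder) > 1 else 0,
            )
        )
    return replace(s, peaks=out)


def strip_oxonium(
    s: Spectrum,
    tol_ppm: float = 20.0,
    oxonium_list: Sequence[float] = OXONIUM_MZ,
) -> tuple[Spectrum, list[Peak]]:
    """Remove glyco-oxonium peaks; return (stripped spectrum, removed peaks).

    Removed peaks are kept for diagnostics, e.g. checking that the
    138.055 trigger ion was present.
    """
    kept: list[Peak] = []
    removed: list[Peak] = []
    for p in s.peaks:
        if any(abs(p.mz - ox) <= ox * tol_ppm * 1e-6 for ox in oxonium_list):
            removed.append(p)
        else:
            kept.append(p)
    return replace(s, peaks=kept), removed


def has_trigger_ion(
    s: Spectrum, tol_ppm: float = 20.0, min_relative_intensity: float = 0.0
) -> bool:
    """True if the 138.055 HexNAc fragment is present (optionally intense)."""
    base = s.base_peak_intensity()
    tol = TRIGGER_ION_MZ * tol_ppm * 1e-6
    return any(
        abs(p.mz - TRIGGER_ION_MZ) <= tol
        and (base == 0 or p.intensity / base >= min_relative_intensity)
        for p in s.peaks
    )


def pair_spectra(
    spectra: Sequence[Spectrum],
    pairing_tol_ppm: float = 10.0,
    max_rt_gap_s: float = 10.0,
) -> tuple[list[SpectrumPair], list[Spectrum]]:
    """Pair each CID2 spectrum with its triggering HCD2 spectrum.

    A CID scan is paired to the HCD scan with the same precursor m/z
    (within ``pairing_tol_ppm``), the same charge, and RT gap at most
    ``max_rt_gap_s``; among candidates the smallest RT gap wins (with a
    logged warning when more than one candidate qualifies).  Returns the
    pairs and the spectra left unpaired.
    """
    hcds = [s for s in spectra if s.kind == "HCD2"]
    cids = [s for s in spectra if s.kind == "CID2"]
    used_hcd: set[int] = set()
    pairs: list[SpectrumPair] = []
    unpaired: list[Spectrum] = []
    for cid in cids:
        candidates = []
        for i, hcd in enumerate(hcds):
            if i in used_hcd or hcd.precursor_charge != cid.precursor_charge:
                continue
            if abs(hcd.precursor_mz - cid.precursor_mz) > (
                cid.precursor_mz * pairing_tol_ppm * 1e-6
            ):
                continue
            gap = abs(hcd.retention_time - cid.retention_time)
            if gap <= max_rt_gap_s:
                candidates.append((gap, i))
        if not candidates:
            unpaired.append(cid)
            continue
        if len(candidates) > 1:
            logger.warning(
                "ambiguous pairing for %r: %d candidates; choosing smallest RT gap",
                cid.title,
                len(candidates),
            )
        _, i = min(candidates)
        used_hcd.add(i)
        pairs.append(SpectrumPair(hcd=hcds[i], cid=cid))
    unpaired.extend(h for i, h in enumerate(hcds) if i not in used_hcd)
    return pairs, unpaired
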