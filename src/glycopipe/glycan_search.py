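"""Glycan identification from HCD/CID spectrum pairs.

For each candidate glycan in the database, the peptide backbone mass is
deduced by subtracting the glycan mass from the precursor mass.  The
candidate survives a Y1 filter (at least three trimannosyl core ions
matched across the pair, or the Y1 / 0,2X0 ion pair at one charge state
in the HCD spectrum), and is then scored on the matched Y-ion evidence of
BOTH spectra:

    score = [ sum_i inten_i * (1 - (|merr_i|/tol_i)^4) ]
            * ratio_ion^alpha * ratio_core^beta

where ratio_ion is the fraction of theoretical ions matched in either
spectrum, ratio_core the fraction of (composition-consistent) trimannosyl
core ions matched, and the quartic weight penalises large mass errors.
alpha = 0.22 and beta = 0.45.  The top-ranked glycan per pair is kept as
the glycan-spectrum match (GSM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .glycans import GlycanComposition, GlycanTree, core_ion_offsets, enumerate_y_ions
from .masses import mz_from_neutral
from .spectra import Peak, SpectrumPair

__all__ = [
    "ScoringParams",
    "IonSpec",
    "MatchedIon",
    "GSM",
    "deduce_backbone",
    "glycan_ion_offsets",
    "match_ions",
    "filter_y1",
    "score_glycan",
    "search_pair",
]


@dataclass(frozen=True)
class ScoringParams:
    alpha: float = 0.22
    beta: float = 0.45
    frag_tol_ppm: float = 20.0
    prec_tol_ppm: float = 10.0
    min_backbone_da: float = 500.0
    normalize_intensity: bool = False  # per-spectrum base-peak normalisation

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.frag_tol_ppm <= 0 or self.prec_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class IonSpec:
    """One theoretical glycan-part offset relative to the naked backbone."""

    offset: float
    label: str
    is_core: bool


@dataclass(frozen=True)
class MatchedIon:
    theoretical_neutral: float
    theoretical_mz: float
    peak: Peak
    charge: int
    merr: float  # observed - theoretical, on the m/z scale
    tol: float  # frag_tol_ppm * theoretical_mz * 1e-6
    source: str  # HCD2 | CID2
    is_core: bool
    ion_label: str


@dataclass
class GSM:
    """Glycan-spectrum match: one glycan ranked against one spectrum pair."""

    pair_id: str
    glycan: GlycanTree
    composition: GlycanComposition
    backbone_neutral: float
    score: float
    matched: list[MatchedIon] = field(default_factory=list)
    n_core_matched: int = 0
    is_decoy: bool = False
    rt: float = 0.0
    precursor_neutral: float = 0.0
    tie: bool = False
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("GSM score must be non-negative")


def deduce_backbone(precursor_neutral: float, glycan_mass: float) -> float | None:
    """Neutral backbone mass implied by a precursor and a glycan candidate.

    The Y1 ion mass is backbone + HexNAc.  Returns None (candidate
    discarded) when the deduction is non-positive.
    """
    backbone = precursor_neutral - glycan_mass
    return backbone if backbone > 0 else None


def glycan_ion_offsets(tree: GlycanTree) -> list[IonSpec]:
    """Theoretical ion offsets for a glycan: Y ions plus core ions.

    The Y-ion set comes from subtree enumeration; the nine trimannosyl
    core ions (restricted to those consistent with the composition) are
    merged in, keeping the core label when a Y mass coincides with a core
    offset.  Distinct masses only: isobaric subtrees collapse.
    """
    specs: list[IonSpec] = [
        IonSpec(off, label, True)
        for label, off in core_ion_offsets(tree.composition).items()
    ]
    have = np.asarray([s.offset for s in specs])
    for g in enumerate_y_ions(tree).distinct_masses:
        if not np.any(np.abs(have - g) <= 1e-6):
            specs.append(IonSpec(float(g), f"Y+{g:.4f}", False))
            have = np.append(have, g)
    specs.sort(key=lambda s: s.offset)
    return specs


def match_ions(
    pair: SpectrumPair,
    backbone: float,
    ions: Sequence[IonSpec],
    params: ScoringParams,
) -> list[MatchedIon]:
    """Greedy smallest-|ppm|-first assignment of peaks to theoretical ions.

    Each theoretical ion is tried at charges 1..precursor_charge in both
    spectra; a peak satisfies at most one theoretical ion, and each
    (ion, spectrum, charge) slot takes at most one peak.
    """
    spectra = [pair.hcd, pair.cid]
    charges = range(1, pair.precursor_charge + 1)
    candidates: list[tuple[float, int, int, int, int]] = []
    for s_idx, s in enumerate(spectra):
        mzs = s.mz_array
        if mzs.size == 0:
            continue
        for ion_idx, ion in enumerate(ions):
            neutral = backbone + ion.offset
            for z in charges:
                tmz = mz_from_neutral(neutral, z)
                tol = tmz * params.frag_tol_ppm * 1e-6
                lo = int(np.searchsorted(mzs, tmz - tol))
                hi = int(np.searchsorted(mzs, tmz + tol))
                for j in range(lo, hi):
                    candidates.append(
                        (abs(mzs[j] - tmz) / tmz, s_idx, ion_idx, z, j)
                    )
    candidates.sort()
    used_peaks: set[tuple[int, int]] = set()
    used_slots: set[tuple[int, int, int]] = set()
    matches: list[MatchedIon] = []
    for _, s_idx, ion_idx, z, j in candidates:
        if (s_idx, j) in used_peaks or (s_idx, ion_idx, z) in used_slots:
            continue
        used_peaks.add((s_idx, j))
        used_slots.add((s_idx, ion_idx, z))
        s = spectra[s_idx]
        ion = ions[ion_idx]
        neutral = backbone + ion.offset
        tmz = mz_from_neutral(neutral, z)
        matches.append(
            MatchedIon(
                theoretical_neutral=neutral,
                theoretical_mz=tmz,
                peak=s.peaks[j],
                charge=z,
                merr=s.peaks[j].mz - tmz,
                tol=tmz * params.frag_tol_ppm * 1e-6,
                source=s.kind,
                is_core=ion.is_core,
                ion_label=ion.label,
            )
        )
    return matches


def filter_y1(
    pair: SpectrumPair,
    glycan: GlycanTree,
    params: ScoringParams,
    backbone: float | None = None,
    matches: list[MatchedIon] | None = None,
) -> tuple[bool, list[MatchedIon]]:
    """Candidate-Y1 filter for one glycan against a spectrum pair.

    Pass iff at least three distinct trimannosyl core ion species are
    matched anywhere in the pair, or the (Y1, 0,2X0) ion pair is matched
    in the HCD spectrum at the same charge state.  Returns the core-ion
    matches either way.
    """
    if backbone is None:
        backbone = deduce_backbone(pair.precursor_neutral, glycan.mass)
        if backbone is None or backbone < params.min_backbone_da:
            return False, []
    if matches is None:
        core_specs = [
            IonSpec(off, label, True)
            for label, off in core_ion_offsets(glycan.composition).items()
        ]
        matches = match_ions(pair, backbone, core_specs, params)
    core_matches = [m for m in matches if m.is_core]
    species = {m.ion_label for m in core_matches}
    if len(species) >= 3:
        return True, core_matches
    hcd_by_label = {
        (m.ion_label, m.charge) for m in core_matches if m.source == "HCD2"
    }
    for z in range(1, pair.precursor_charge + 1):
        if ("Y1", z) in hcd_by_label and ("0,2X0", z) in hcd_by_label:
            return True, core_matches
    return False, core_matches


def _score_from_matches(
    pair: SpectrumPair,
    matches: list[MatchedIon],
    ions: Sequence[IonSpec],
    params: ScoringParams,
) -> tuple[float, int]:
    """Evaluate the weighted-intensity score given an ion assignment."""
    if params.normalize_intensity:
        base = {
            "HCD2": pair.hcd.base_peak_intensity() or 1.0,
            "CID2": pair.cid.base_peak_intensity() or 1.0,
        }
    else:
        base = {"HCD2": 1.0, "CID2": 1.0}
    total = 0.0
    for m in matches:
        w = 1.0 - (abs(m.merr) / m.tol) ** 4
        total += (m.peak.intensity / base[m.source]) * max(w, 0.0)
    n_theory = len(ions)
    n_core_theory = sum(1 for i in ions if i.is_core)
    matched_labels = {m.ion_label for m in matches}
    n_matched = len(matched_labels)
    core_matched = {m.ion_label for m in matches if m.is_core}
    ratio_ion = n_matched / n_theory if n_theory else 0.0
    ratio_core = len(core_matched) / n_core_theory if n_core_theory else 0.0
    score = total * ratio_ion**params.alpha * ratio_core**params.beta
    return score, len(core_matched)


def score_glycan(
    pair: SpectrumPair,
    glycan: GlycanTree,
    backbone: float,
    params: ScoringParams,
    offsets: Sequence[IonSpec] | None = None,
    is_decoy: bool = False,
) -> GSM:
    """Score one glycan candidate (or its decoy ion set) against a pair."""
    ions = glycan_ion_offsets(glycan) if offsets is None else list(offsets)
    matches = match_ions(pair, backbone, ions, params)
    score, n_core = _score_from_matches(pair, matches, ions, params)
    return GSM(
        pair_id=pair.pair_id,
        glycan=glycan,
        composition=glycan.composition,
        backbone_neutral=backbone,
        score=score,
        matched=matches,
        n_core_matched=n_core,
        is_decoy=is_decoy,
        rt=pair.retention_time,
        precursor_neutral=pair.precursor_neutral,
    )


def search_pair(
    pair: SpectrumPair,
    db: Sequence[GlycanTree],
    params: ScoringParams | None = None,
) -> tuple[GSM | None, list[GSM]]:
    """Rank every surviving database glycan against one spectrum pair.

    Candidates must leave a backbone above the floor, pass the Y1 filter,
    and score above zero.  Ties are broken by more core ions matched, then
    database order.  Returns (top GSM or None, full ranked list).
    """
    params = params or ScoringParams()
    ranked: list[tuple[float, int, int, GSM]] = []
    for db_idx, glycan in enumerate(db):
        backbone = deduce_backbone(pair.precursor_neutral, glycan.mass)
        if backbone is None or backbone < params.min_backbone_da:
            continue
        ions = glycan_ion_offsets(glycan)
        matches = match_ions(pair, backbone, ions, params)
        ok, _ = filter_y1(pair, glycan, params, backbone=backbone, matches=matches)
        if not ok:
            continue
        score, n_core = _score_from_matches(pair, matches, ions, params)
        if score <= 0:
            continue
        gsm = GSM(
            pair_id=pair.pair_id,
            glycan=glycan,
            composition=glycan.composition,
            backbone_neutral=backbone,
            score=score,
            matched=matches,
            n_core_matched=n_core,
            rt=pair.retention_time,
            precursor_neutral=pair.precursor_neutral,
        )
        ranked.append((-score, -n_core, db_idx, gsm))
    ranked.sort(key=lambda t: t[:3])
    gsms = [t[3] for t in ranked]
    if not gsms:
        return None, []
    top = gsms[0]
    if len(ranked) > 1 and abs(-ranked[1][0] - top.score) <= 1e-9 * max(top.score, 1.0):
        top.tie = True
    return top, gsms
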