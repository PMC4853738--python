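"""Alignment of glycan and peptide identifications into glycopeptides.

Glycans are identified from HCD/CID spectrum pairs in one LC-MS run;
peptide backbones (Y1 identities) come from MS3 spectra of a second run.
A GSM and a PSM describe the same glycopeptide when the deduced backbone
mass agrees with the peptide mass within a ppm tolerance and the two
scans elute within a retention-time window (microheterogeneity clusters
of one backbone typically span 1-6 minutes).  Aligned pairs are GPSMs;
grouping GPSMs by (peptide, site, glycan composition) yields the
non-redundant glycopeptide and site tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .glycan_search import GSM
from .masses import PROTON, ppm_error
from .ms3 import PSM

__all__ = [
    "GPSM",
    "Glycopeptide",
    "align",
    "collapse_glycopeptides",
    "ion_complementarity_report",
    "gpsm_table",
    "glycopeptide_table",
]


@dataclass
class GPSM:
    """A glycan-spectrum match aligned to a peptide-spectrum match."""

    gsm: GSM
    psm: PSM
    mass_error_ppm: float
    rt_gap: float

    @property
    def site_key(self) -> tuple[str, int, tuple[int, ...]]:
        pep = self.psm.peptide
        j_local = next(
            (pos for pos, delta in self.psm.mods if pep.sequence[pos] == "J"),
            pep.sequence.find("J"),
        )
        site = pep.start + j_local + 1  # 1-based protein coordinate
        return (pep.sequence, site, self.gsm.composition.as_tuple())


@dataclass
class Glycopeptide:
    """Non-redundant glycopeptide: one (peptide, site, composition)."""

    peptide: str
    protein: str
    site: int  # 1-based position of the modified J in the protein
    composition: tuple[int, ...]
    best_score: float
    supports: list[GPSM] = field(default_factory=list)

    @property
    def n_supports(self) -> int:
        return len(self.supports)


def align(
    gsms: Sequence[GSM],
    psms: Sequence[PSM],
    mass_tol_ppm: float = 20.0,
    rt_window_s: float = 360.0,
    rt_offset_s: float = 0.0,
) -> list[GPSM]:
    """Match each GSM to the best compatible PSM.

    Compatibility: |ppm(deduced backbone, peptide mass)| <= tolerance and
    |RT gap - offset| <= window.  The best PSM has the smallest |ppm|,
    then the smallest RT gap.  A GSM yields at most one GPSM; one PSM may
    support many GSMs (microheterogeneity).  ``rt_offset_s`` optionally
    removes a constant between-run RT shift.
    """
    if not gsms or not psms:
        return []
    psms_sorted = sorted(psms, key=lambda p: (p.backbone_neutral, p.spectrum_id))
    masses = np.asarray([p.backbone_neutral for p in psms_sorted])
    out: list[GPSM] = []
    for gsm in sorted(gsms, key=lambda g: g.pair_id):
        tol_da = gsm.backbone_neutral * mass_tol_ppm * 1e-6
        lo = int(np.searchsorted(masses, gsm.backbone_neutral - tol_da))
        hi = int(np.searchsorted(masses, gsm.backbone_neutral + tol_da))
        best: tuple[float, float, int] | None = None
        for idx in range(lo, hi):
            psm = psms_sorted[idx]
            gap = abs(gsm.rt - psm.rt - rt_offset_s)
            if gap > rt_window_s:
                continue
            err = abs(ppm_error(gsm.backbone_neutral, psm.backbone_neutral))
            key = (err, gap, idx)
            if best is None or key < best:
                best = key
        if best is not None:
            idx = best[2]
            psm = psms_sorted[idx]
            out.append(
                GPSM(
                    gsm=gsm,
                    psm=psm,
                    mass_error_ppm=ppm_error(
                        gsm.backbone_neutral, psm.backbone_neutral
                    ),
                    rt_gap=abs(gsm.rt - psm.rt - rt_offset_s),
                )
            )
    return out


def median_rt_offset(gpsms: Sequence[GPSM]) -> float:
    """Constant between-run RT shift from high-confidence anchors."""
    if not gpsms:
        return 0.0
    return float(np.median([g.gsm.rt - g.psm.rt for g in gpsms]))


def collapse_glycopeptides(
    gpsms: Sequence[GPSM], glycan_q_cut: float = 0.01
) -> list[Glycopeptide]:
    """Group q-filtered GPSMs into non-redundant glycopeptides.

    The identity key is (peptide sequence, protein site, glycan
    COMPOSITION) — structure isomers with one composition collapse, as in
    microheterogeneity tables.
    """
    groups: dict[tuple, Glycopeptide] = {}
    for g in gpsms:
        q = g.gsm.q_value
        if np.isnan(q) or q > glycan_q_cut:
            continue
        key = g.site_key
        if key not in groups:
            pep = g.psm.peptide
            groups[key] = Glycopeptide(
                peptide=key[0],
                protein=pep.protein,
                site=key[1],
                composition=key[2],
                best_score=g.gsm.score,
            )
        gp = groups[key]
        gp.supports.append(g)
        gp.best_score = max(gp.best_score, g.gsm.score)
    return sorted(
        groups.values(), key=lambda gp: (gp.protein, gp.site, gp.composition)
    )


def site_table(glycopeptides: Sequence[Glycopeptide]) -> pd.DataFrame:
    """Per-site microheterogeneity: how many compositions per sequon."""
    rows = [
        {
            "protein": gp.protein,
            "site": gp.site,
            "peptide": gp.peptide,
            "composition": "(%d,%d,%d,%d,%d)" % gp.composition,
            "n_gpsms": gp.n_supports,
            "best_score": gp.best_score,
        }
        for gp in glycopeptides
    ]
    df = pd.DataFrame(
        rows,
        columns=["protein", "site", "peptide", "composition", "n_gpsms", "best_score"],
    )
    return df


def ion_complementarity_report(gsms: Sequence[GSM]) -> pd.DataFrame:
    """Core / non-core matched-ion accounting by fragmentation kind.

    For each GSM, core ion species are counted as matched in HCD only, in
    CID only, or in both; non-core ions are counted per kind.  HCD at
    high collision energy favours the innermost ions (Y0, Y1, 0,2X0)
    while CID supplies the outer Y ladder, so the two columns measure the
    complementarity of the pair.
    """
    rows = []
    for g in gsms:
        core_hcd = {m.ion_label for m in g.matched if m.is_core and m.source == "HCD2"}
        core_cid = {m.ion_label for m in g.matched if m.is_core and m.source == "CID2"}
        noncore_hcd = {
            m.ion_label for m in g.matched if not m.is_core and m.source == "HCD2"
        }
        noncore_cid = {
            m.ion_label for m in g.matched if not m.is_core and m.source == "CID2"
        }
        rows.append(
            {
                "pair_id": g.pair_id,
                "core_hcd_only": len(core_hcd - core_cid),
                "core_cid_only": len(core_cid - core_hcd),
                "core_both": len(core_hcd & core_cid),
                "noncore_hcd": len(noncore_hcd),
                "noncore_cid": len(noncore_cid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "core_hcd_only",
            "core_cid_only",
            "core_both",
            "noncore_hcd",
            "noncore_cid",
        ],
    )


def gpsm_table(gpsms: Sequence[GPSM]) -> pd.DataFrame:
    """GPSM report; backbone masses printed as MH+ per convention."""
    rows = [
        {
            "pair_id": g.gsm.pair_id,
            "ms3_spectrum": g.psm.spectrum_id,
            "peptide": g.psm.modified_sequence,
            "protein": g.psm.peptide.protein,
            "composition": str(g.gsm.composition),
            "glycan_id": g.gsm.glycan.id,
            "backbone_mh": g.gsm.backbone_neutral + PROTON,
            "peptide_mh": g.psm.backbone_neutral + PROTON,
            "mass_error_ppm": g.mass_error_ppm,
            "rt_gap_s": g.rt_gap,
            "glycan_score": g.gsm.score,
            "glycan_q": g.gsm.q_value,
            "psm_q": g.psm.q_value,
        }
        for g in gpsms
    ]
    return pd.DataFrame(rows)


def glycopeptide_table(glycopeptides: Sequence[Glycopeptide]) -> pd.DataFrame:
    return site_table(glycopeptides)
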