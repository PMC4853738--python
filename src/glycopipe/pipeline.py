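"""End-to-end orchestration of the four-step workflow.

Step 1/2: read run-1 MGF, deisotope, strip oxonium ions, pair HCD with
CID scans, and run the competitive target-decoy glycan search per pair.
Glycan q-values come from the finite-mixture FDR model.  Step 3: read
run-2 MGF and identify MS3 spectra of Y1 ions against the digested
protein database at 1% PSM FDR.  Step 4: align glycan and peptide
identifications by backbone mass and retention time into GPSMs, then
collapse to non-redundant glycopeptides and the site table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fdr as fdr_mod
from . import integrate as integrate_mod
from .fdr import DecoyConfig, MixtureFit, assign_q_values, counting_q_values, fit_fmm
from .glycan_search import GSM, ScoringParams
from .glycans import load_glycan_db
from .masses import PROTON
from .ms3 import DigestParams, ModSpec, PeptideIndex, psm_fdr, read_fasta, search_ms3
from .spectra import deisotope, pair_spectra, read_mgf, strip_oxonium

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_glycan_stage",
           "run_ms3_stage"]


@dataclass
class RunConfig:
    run1_mgf: str
    run2_mgf: str
    glycan_db: str
    fasta: str
    out_dir: str = "glycopipe_out"
    seed: int = 0
    glycan_q_cut: float = 0.01
    psm_q_cut: float = 0.01
    decoy_method: str = "random_shift_1_30"
    scoring: ScoringParams = field(default_factory=ScoringParams)
    digest: DigestParams = field(default_factory=DigestParams)
    mods: ModSpec = field(default_factory=ModSpec)
    pairing_tol_ppm: float = 10.0
    max_rt_gap_s: float = 10.0
    align_mass_tol_ppm: float = 20.0
    align_rt_window_s: float = 360.0
    strip_oxonium_from_cid: bool = True
    deisotope_spectra: bool = True
    fmm_min_scores: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("scoring", ScoringParams), ("digest", DigestParams),
                         ("mods", ModSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        cfg = cls(**raw)
        for p in (cfg.run1_mgf, cfg.run2_mgf, cfg.glycan_db, cfg.fasta):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg


@dataclass
class PipelineResult:
    gsms: list[GSM]
    fit: MixtureFit | None
    psms: list
    gpsms: list
    glycopeptides: list
    summary: dict


def _prepare_pairs(cfg: RunConfig):
    spectra = read_mgf(cfg.run1_mgf)
    processed = []
    for s in spectra:
        if cfg.deisotope_spectra:
            s = deisotope(s, tol_ppm=cfg.scoring.frag_tol_ppm)
        if s.kind == "HCD2" or (s.kind == "CID2" and cfg.strip_oxonium_from_cid):
            s, _removed = strip_oxonium(s, tol_ppm=cfg.scoring.frag_tol_ppm)
        processed.append(s)
    pairs, unpaired = pair_spectra(
        processed, pairing_tol_ppm=cfg.pairing_tol_ppm, max_rt_gap_s=cfg.max_rt_gap_s
    )
    return pairs, unpaired


def run_glycan_stage(cfg: RunConfig):
    """Steps 1-2: spectrum pairing, glycan search, decoys, FMM q-values."""
    t0 = time.perf_counter()
    db = load_glycan_db(cfg.glycan_db)
    pairs, unpaired = _prepare_pairs(cfg)
    decoy_cfg = DecoyConfig(method=cfg.decoy_method, rng_seed=cfg.seed)
    gsms: list[GSM] = []
    target_scores: list[float] = []
    decoy_scores: list[float] = []
    for pair in pairs:
        gsm, best_t, best_d = fdr_mod.search_pair_with_decoy(
            pair, db, decoy_cfg, cfg.scoring
        )
        if gsm is not None:
            gsms.append(gsm)
        if best_t > 0:
            target_scores.append(best_t)
        decoy_scores.append(best_d)
    fit = None
    if (
        len(target_scores) >= cfg.fmm_min_scores
        and len(decoy_scores) >= cfg.fmm_min_scores
    ):
        fit = fit_fmm(target_scores, decoy_scores, min_scores=cfg.fmm_min_scores)
        assign_q_values(gsms, fit)
    else:
        # too few scores for the mixture model: classical competitive
        # target-decoy counting
        logger.warning(
            "only %d target / %d decoy scores (< %d): falling back to "
            "counting-based q-values",
            len(target_scores), len(decoy_scores), cfg.fmm_min_scores,
        )
        counting_q_values(gsms)
    logger.info(
        "glycan stage: %d pairs, %d GSMs (%d decoy) in %.1fs",
        len(pairs),
        len(gsms),
        sum(g.is_decoy for g in gsms),
        time.perf_counter() - t0,
    )
    return gsms, fit, pairs, unpaired


def run_ms3_stage(cfg: RunConfig):
    """Step 3: MS3 peptide search with target-decoy PSM FDR."""
    t0 = time.perf_counter()
    proteins = read_fasta(cfg.fasta)
    index = PeptideIndex.build(proteins, cfg.digest, cfg.mods, with_decoys=True)
    ms3_spectra = [s for s in read_mgf(cfg.run2_mgf) if s.kind == "MS3"]
    best_psms = []
    for s in ms3_spectra:
        ranked = search_ms3(s, index)
        if ranked:
            best_psms.append(ranked[0])
    accepted = psm_fdr(best_psms, q_cut=cfg.psm_q_cut)
    logger.info(
        "ms3 stage: %d spectra, %d PSMs, %d accepted (HexNAc-J, q<=%.3g) in %.1fs",
        len(ms3_spectra),
        len(best_psms),
        len(accepted),
        cfg.psm_q_cut,
        time.perf_counter() - t0,
    )
    return accepted, best_psms


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute all four steps and (optionally) write the result bundle."""
    gsms, fit, pairs, unpaired = run_glycan_stage(cfg)
    accepted_psms, all_psms = run_ms3_stage(cfg)
    target_gsms = [g for g in gsms if not g.is_decoy]
    gpsms = integrate_mod.align(
        target_gsms,
        accepted_psms,
        mass_tol_ppm=cfg.align_mass_tol_ppm,
        rt_window_s=cfg.align_rt_window_s,
    )
    glycopeptides = integrate_mod.collapse_glycopeptides(
        gpsms, glycan_q_cut=cfg.glycan_q_cut
    )
    confident = [
        g
        for g in gpsms
        if not np.isnan(g.gsm.q_value) and g.gsm.q_value <= cfg.glycan_q_cut
    ]
    summary = {
        "n_pairs": len(pairs),
        "n_unpaired": len(unpaired),
        "n_gsms": len(target_gsms),
        "n_decoy_gsms": sum(g.is_decoy for g in gsms),
        "n_gsms_q": sum(
            (not np.isnan(g.q_value)) and g.q_value <= cfg.glycan_q_cut
            for g in target_gsms
        ),
        "n_psms": len(accepted_psms),
        "n_gpsms": len(gpsms),
        "n_gpsms_q": len(confident),
        "n_glycopeptides": len(glycopeptides),
        "n_sites": len({(gp.protein, gp.site) for gp in glycopeptides}),
        "fmm_pi0": fit.pi0 if fit else None,
        "fmm_converged": fit.converged if fit else None,
    }
    result = PipelineResult(
        gsms=gsms,
        fit=fit,
        psms=accepted_psms,
        gpsms=gpsms,
        glycopeptides=glycopeptides,
        summary=summary,
    )
    if write_outputs:
        _write_bundle(cfg, result, unpaired)
    return result


def _gsm_table(gsms: Sequence[GSM]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": g.pair_id,
            "rt": g.rt,
            "precursor_neutral": g.precursor_neutral,
            "glycan_id": g.glycan.id,
            "composition": str(g.composition),
            "backbone_mh": g.backbone_neutral + PROTON,
            "score": g.score,
            "n_core": g.n_core_matched,
            "n_matched": len(g.matched),
            "is_decoy": g.is_decoy,
            "q_value": g.q_value,
        }
        for g in gsms
    ]
    return pd.DataFrame(rows)


def _write_bundle(cfg: RunConfig, result: PipelineResult, unpaired) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _gsm_table(result.gsms).to_csv(out / "gsms.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "spectrum_id": p.spectrum_id,
                "peptide": p.modified_sequence,
                "protein": p.peptide.protein,
                "backbone_mh": p.backbone_neutral + PROTON,
                "score": p.psm_score,
                "q_value": p.q_value,
                "has_hexnac_on_j": p.has_hexnac_on_j,
            }
            for p in result.psms
        ]
    ).to_csv(out / "psms.tsv", sep="\t", index=False)
    integrate_mod.gpsm_table(result.gpsms).to_csv(
        out / "gpsms.tsv", sep="\t", index=False
    )
    integrate_mod.glycopeptide_table(result.glycopeptides).to_csv(
        out / "glycopeptides.tsv", sep="\t", index=False
    )
    integrate_mod.ion_complementarity_report(
        [g for g in result.gsms if not g.is_decoy]
    ).to_csv(out / "ion_complementarity.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"title": s.title, "kind": s.kind} for s in unpaired]
    ).to_csv(out / "unpaired_spectra.tsv", sep="\t", index=False)
    diag = dict(result.summary)
    if result.fit is not None:
        diag["fmm"] = {
            "pi0": result.fit.pi0,
            "gamma_shape": result.fit.gamma_shape,
            "gamma_loc": result.fit.gamma_loc,
            "gamma_scale": result.fit.gamma_scale,
            "norm_mu": result.fit.norm_mu,
            "norm_sigma": result.fit.norm_sigma,
            "n_em_iterations": len(result.fit.loglik_trace),
            "converged": result.fit.converged,
        }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(diag, fh, indent=2)
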