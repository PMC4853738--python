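"""Synthetic glycoproteomics fixtures with planted ground truth.

Emulates the two-run product-dependent acquisition the pipeline expects:
run 1 collects HCD/CID MS2 spectrum pairs, run 2 collects MS3 spectra of
Y1 ions; both runs sample the same planted glycopeptides at jittered
retention times.  Fragmentation preferences follow the observed
behaviour: HCD at high collision energy yields dominant oxonium ions and
intense innermost Y ions (Y0, Y1, 0,2X0) with the Y1 among the most
intense peaks above 700 m/z, CID yields extended outer Y-ion ladders and
almost no cross-ring ion, and MS3 spectra of Y1 ions show b/y ladders
with HexNAc neutral-loss satellites.  Mass errors are ppm-scale Gaussian
in the Orbitrap MS2 scans and Da-scale in the ion-trap MS3 scans; every
spectrum also receives uniform-m/z noise peaks.

Planted-false spectra for FDR benchmarking exploit an exact isobaric
composition swap found by searching the composition lattice
(NeuGc + dHex vs NeuAc + Hex, |delta| < 1e-5 Da): a spectrum generated
from a structure absent from the database is best explained by its
isobaric confounder present in the database, giving wrong-composition
matches that survive the Y1 filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .glycans import (
    GlycanTree,
    core_ion_offsets,
    enumerate_y_ions,
    parse_glycan,
    write_glycan_db,
)
from .masses import MONOSACCHARIDES, mz_from_neutral, peptide_neutral_mass
from .ms3 import sequon_substitute, theoretical_ms3_ions
from .spectra import OXONIUM_MZ, Peak, Spectrum, write_mgf

__all__ = [
    "SimConfig",
    "GroundTruth",
    "random_glycan_db",
    "random_proteins",
    "find_isobaric_swap",
    "simulate_run",
]

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Peak-pick probabilities and intensity preferences mirror the
    fragmentation behaviour described above; mass accuracy defaults to a
    5 ppm Orbitrap-like error.  All randomness flows from ``rng_seed``.
    """

    rng_seed: int = 0
    n_glycopeptides: int = 100
    n_false: int = 0  # planted isobaric confounders
    glycan_db_size: int = 50
    n_proteins: int = 6
    n_weak: int = 0  # degraded-quality plants (weak fragmentation evidence)
    weak_pick_scale: float = 0.35
    weak_noise_mult: int = 2
    allow_neugc_db: bool = False  # human-serum-like DB: no NeuGc glycans
    ppm_noise_sd: float = 5.0
    ms3_da_noise_sd: float = 0.1
    noise_peaks: int = 150
    noise_chemical_fraction: float = 0.7
    gradient_s: float = 3600.0
    rt_jitter_s: float = 180.0  # per-glycoform jitter around the backbone RT
    # per-ion-class pick probabilities
    hcd_pick: dict = field(
        default_factory=lambda: {
            "Y0": 0.8,
            "Y1": 0.95,
            "0,2X0": 0.7,
            "outer": 0.2,
            "oxonium": 1.0,
        }
    )
    cid_pick: dict = field(
        default_factory=lambda: {"inner": 0.5, "outer": 0.8, "0,2X0": 0.02}
    )
    ms3_pick: dict = field(default_factory=lambda: {"by": 0.85, "neutral_loss": 0.5})

    def __post_init__(self) -> None:
        for d in (self.hcd_pick, self.cid_pick, self.ms3_pick):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"pick probability {k}={v} outside [0, 1]")


@dataclass
class GroundTruth:
    table: pd.DataFrame
    glycan_db_path: Path
    fasta_path: Path
    run1_mgf: Path  # HCD + CID pairs
    run2_mgf: Path  # HCD + MS3


# ---------------------------------------------------------------------------
# Databases
# ---------------------------------------------------------------------------

def _random_antenna(rng: np.random.Generator, allow_neugc: bool = True) -> str:
    """One antenna: HexNAc, optional Hex, optional terminal sialic acid."""
    s = "(N"
    r = rng.random()
    if r < 0.85:
        inner = "(H"
        r2 = rng.random()
        if r2 < 0.45:
            inner += "(A)"
        elif allow_neugc and r2 < 0.55:
            inner += "(G)"
        elif r2 < 0.65:
            inner += "(F)"
        inner += ")"
        s += inner
    s += ")"
    return s


def random_glycan_tree(rng: np.random.Generator, allow_neugc: bool = True) -> GlycanTree:
    """A random plausible N-glycan on the trimannosyl core.

    Root HexNAc (optional core fucose), second HexNAc, branching Man3
    core; each core mannose carries 0-2 antennae or, for high-mannose
    forms, extra Hex chains.
    """
    if rng.random() < 0.3:  # high-mannose
        arms = []
        for _ in range(2):
            n = int(rng.integers(0, 4))
            arm = "".join("(H" for _ in range(n)) + ")" * n
            arms.append(arm)
        core = f"(H{arms[0]}{arms[1]})"
        enc = f"(N(N(H(H){core})))"
    else:  # complex / hybrid
        fuc = "(F)" if rng.random() < 0.35 else ""
        arm1 = "".join(
            _random_antenna(rng, allow_neugc) for _ in range(int(rng.integers(0, 3)))
        )
        arm2 = "".join(
            _random_antenna(rng, allow_neugc) for _ in range(int(rng.integers(0, 3)))
        )
        bisect = "(N)" if rng.random() < 0.15 else ""
        enc = f"(N{fuc}(N(H(H{arm1})(H{arm2}){bisect})))"
    return parse_glycan(enc)


def random_glycan_db(
    rng: np.random.Generator, size: int, allow_neugc: bool = True
) -> list[GlycanTree]:
    """``size`` distinct (non-isomorphic) random N-glycans."""
    trees: list[GlycanTree] = []
    seen: set[str] = set()
    attempts = 0
    while len(trees) < size and attempts < size * 200:
        attempts += 1
        t = random_glycan_tree(rng, allow_neugc)
        key = t.canonical()
        if key not in seen:
            seen.add(key)
            t.id = f"G{len(trees) + 1}"
            trees.append(t)
    return trees


_AA_POOL = "ADEFGHILQSTVWY"  # no K/R/P/N/C/M: controlled placement below


def random_proteins(
    rng: np.random.Generator, n_proteins: int, peptides_per_protein: int = 8
) -> dict[str, str]:
    """Random proteins built from tryptic segments with N-X-S/T sequons.

    Each protein is a concatenation of segments ending in K/R; roughly
    half the segments carry one sequon, so digestion yields tryptic
    peptides of length 8-20 with a single glycosylation site.
    """
    proteins: dict[str, str] = {}
    for p in range(n_proteins):
        parts: list[str] = []
        for s in range(peptides_per_protein):
            length = int(rng.integers(8, 20))
            seq = [str(_AA_POOL[i]) for i in rng.integers(0, len(_AA_POOL), length)]
            if s % 2 == 0:  # plant a sequon away from the termini
                pos = int(rng.integers(1, length - 3))
                seq[pos] = "N"
                seq[pos + 1] = str(_AA_POOL[int(rng.integers(0, len(_AA_POOL)))])
                seq[pos + 2] = "T" if rng.random() < 0.5 else "S"
            seq[-1] = "K" if rng.random() < 0.5 else "R"
            parts.append("".join(seq))
        proteins[f"SYN{p + 1}"] = "".join(parts)
    return proteins


# ---------------------------------------------------------------------------
# Isobaric confounders
# ---------------------------------------------------------------------------

def find_isobaric_swap(max_count: int = 2, tol_da: float = 1e-4) -> tuple[int, ...]:
    """Search the composition lattice for a near-exact isobaric swap.

    Returns the delta vector (dHex, dHexNAc, dNeuAc, dNeuGc, ddHex) with
    the smallest nonzero |mass| among vectors with entries in
    [-max_count, max_count]; asserts the winner is below ``tol_da``.
    The known solution is NeuGc + dHex = NeuAc + Hex (|delta| ~ 1e-6 Da).
    """
    masses = np.array([MONOSACCHARIDES[m] for m in
                       ("Hex", "HexNAc", "NeuAc", "NeuGc", "dHex")])
    best: tuple[float, tuple[int, ...]] | None = None
    rng = range(-max_count, max_count + 1)
    for d in np.array(np.meshgrid(*[list(rng)] * 5)).T.reshape(-1, 5):
        if not d.any():
            continue
        m = abs(float(d @ masses))
        if best is None or m < best[0]:
            best = (m, tuple(int(x) for x in d))
    assert best is not None and best[0] < tol_da, "no isobaric swap found"
    return best[1]


def make_false_glycan(db_tree: GlycanTree, db_keys: set[str]) -> GlycanTree | None:
    """Isobaric structure absent from the DB whose confounder is present.

    Replaces one terminal Hex by dHex and one terminal NeuAc by NeuGc in
    ``db_tree`` (the inverse of the lattice swap), so the result has the
    same mass but a different composition.  Returns None when the tree
    lacks the needed terminals or the result is itself in the DB.
    """
    t = parse_glycan(db_tree.canonical())  # deep copy
    hex_leaf = neuac_leaf = None
    for node in t.walk():
        if not node.children:
            continue
        for child in node.children:
            if child.children:
                continue
            if child.symbol == "Hex" and hex_leaf is None:
                hex_leaf = child
            elif child.symbol == "NeuAc" and neuac_leaf is None:
                neuac_leaf = child
    if hex_leaf is None or neuac_leaf is None:
        return None
    hex_leaf.symbol = "dHex"
    neuac_leaf.symbol = "NeuGc"
    if t.canonical() in db_keys:
        return None
    t.id = f"FALSE_{db_tree.id}"
    return t


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean_log: float, sd_log: float = 0.4) -> float:
    return float(rng.lognormal(mean_log, sd_log))


def _jitter_ppm(rng: np.random.Generator, mz: float, sd: float) -> float:
    return mz * (1.0 + rng.normal(0.0, sd) * 1e-6)


#: Mean mass defect of peptide-like fragments per nominal mass unit; real
#: MS2 background is dominated by chemical (fragment-like) noise whose
#: masses cluster on this comb, unlike uniformly distributed electronic
#: noise.
MASS_DEFECT_PER_DA = 1.00048


def _add_noise(
    rng: np.random.Generator,
    peaks: list[Peak],
    n: int,
    lo: float,
    hi: float,
    chemical_fraction: float = 0.7,
) -> None:
    """Background peaks: a chemical-noise comb plus uniform electronic noise."""
    for _ in range(n):
        if rng.random() < chemical_fraction:
            # chemical noise: fragment-like, on the defect comb, spanning
            # the full dynamic range like real unassigned fragments
            nominal = int(rng.integers(int(lo), int(hi / MASS_DEFECT_PER_DA)))
            mz = nominal * MASS_DEFECT_PER_DA + float(rng.normal(0.0, 0.005))
            inten = _lognormal(rng, 3.0, 1.3)
        else:
            # electronic noise: uniform in m/z, uniformly faint
            mz = float(rng.uniform(lo, hi))
            inten = _lognormal(rng, 2.0, 0.6)
        peaks.append(Peak(max(mz, 1.0), inten))


def _ms2_spectrum(
    rng: np.random.Generator,
    cfg: SimConfig,
    kind: str,
    title: str,
    glycan: GlycanTree,
    backbone: float,
    charge: int,
    rt: float,
    pick_scale: float = 1.0,
    noise_mult: int = 1,
) -> Spectrum:
    """One HCD or CID MS2 spectrum of a planted glycopeptide."""
    precursor = backbone + glycan.mass
    base_pick = cfg.hcd_pick if kind == "HCD2" else cfg.cid_pick
    pick = {k: min(1.0, v * pick_scale) for k, v in base_pick.items()}
    if "oxonium" in pick:
        pick["oxonium"] = base_pick["oxonium"]  # oxonium yield is robust
    core = core_ion_offsets(glycan.composition)
    outer = [
        float(g)
        for g in enumerate_y_ions(glycan).distinct_masses
        if not any(abs(g - off) <= 1e-6 for off in core.values())
    ]
    peaks: list[Peak] = []

    def emit(offset: float, mean_log: float, p: float, prefer_z: int | None = None) -> None:
        if rng.random() >= p:
            return
        z = prefer_z or int(rng.integers(1, charge + 1))
        mz = mz_from_neutral(backbone + offset, z)
        peaks.append(Peak(_jitter_ppm(rng, mz, cfg.ppm_noise_sd), _lognormal(rng, mean_log)))

    if kind == "HCD2":
        for label, off in core.items():
            if label == "Y1":
                # dominant: among the most intense ions above 700 m/z,
                # the premise of the data-dependent MS3 trigger
                z = 1 if mz_from_neutral(backbone + off, 1) < 2000 else 2
                emit(off, 7.5, pick["Y1"], prefer_z=z)
            elif label == "Y0":
                emit(off, 6.0, pick["Y0"])
            elif label == "0,2X0":
                emit(off, 5.5, pick["0,2X0"])
            else:
                emit(off, 5.0, pick["outer"])
        for g in outer:
            emit(g, 4.5, pick["outer"])
        if rng.random() < pick["oxonium"]:
            for ox in OXONIUM_MZ:
                inten = 9.0 if abs(ox - 138.0550) < 1e-3 else 6.5
                peaks.append(Peak(_jitter_ppm(rng, ox, cfg.ppm_noise_sd), _lognormal(rng, inten)))
    else:  # CID2
        for label, off in core.items():
            p = pick["0,2X0"] if label == "0,2X0" else pick["inner"]
            emit(off, 5.5, p)
        for g in outer:
            emit(g, 6.0, pick["outer"])
    _add_noise(
        rng,
        peaks,
        cfg.noise_peaks * noise_mult,
        150.0,
        2000.0,
        cfg.noise_chemical_fraction,
    )
    return Spectrum(
        title=f"{title} kind={kind}",
        precursor_mz=mz_from_neutral(precursor, charge),
        precursor_charge=charge,
        retention_time=rt,
        peaks=peaks,
        kind=kind,
    )


def _ms3_spectrum(
    rng: np.random.Generator,
    cfg: SimConfig,
    title: str,
    sequence: str,
    mods: Sequence[tuple[int, float]],
    rt: float,
) -> Spectrum:
    """MS3 spectrum of the Y1 ion: b/y ladder + HexNAc-loss satellites."""
    y1_neutral = peptide_neutral_mass(sequence, mods)
    z = 1 if y1_neutral < 2000 else 2
    peaks: list[Peak] = []
    for mz, label in theoretical_ms3_ions(sequence, mods):
        p = cfg.ms3_pick["neutral_loss"] if "HexNAc" in label else cfg.ms3_pick["by"]
        if rng.random() < p:
            peaks.append(
                Peak(mz + float(rng.normal(0.0, cfg.ms3_da_noise_sd)), _lognormal(rng, 5.0))
            )
    _add_noise(
        rng,
        peaks,
        max(1, cfg.noise_peaks // 2),
        200.0,
        max(1200.0, y1_neutral),
        cfg.noise_chemical_fraction,
    )
    return Spectrum(
        title=f"{title} kind=MS3",
        precursor_mz=mz_from_neutral(y1_neutral, z),
        precursor_charge=z,
        retention_time=rt,
        peaks=peaks,
        kind="MS3",
    )


# ---------------------------------------------------------------------------
# Full simulated experiment
# ---------------------------------------------------------------------------

def _glycopeptide_candidates(proteins: dict[str, str]) -> list[tuple[str, str, int]]:
    """Fully tryptic single-J peptides: (protein, J-peptide, start)."""
    out = []
    for acc, seq in proteins.items():
        sub = sequon_substitute(seq)
        start = 0
        for i in range(len(sub)):
            last = i == len(sub) - 1
            if last or (sub[i] in "KR" and sub[i + 1] != "P"):
                pep = sub[start : i + 1]
                if pep.count("J") == 1 and 7 <= len(pep) <= 25:
                    out.append((acc, pep, start))
                start = i + 1
    return out


def simulate_run(
    cfg: SimConfig,
    out_dir: str | Path,
    glycan_db: list[GlycanTree] | None = None,
    proteins: dict[str, str] | None = None,
) -> GroundTruth:
    """Write a complete synthetic experiment to ``out_dir``.

    Produces the glycan database text file, the protein FASTA, run 1
    (HCD + CID MS2 pairs), run 2 (MS3 scans of the Y1 ions at jittered
    retention times) and a ground-truth table with one row per planted
    glycopeptide.  ``cfg.n_false`` of the plants are isobaric-confounder
    spectra labelled false.  Deterministic under a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)
    if glycan_db is None:
        glycan_db = random_glycan_db(rng, cfg.glycan_db_size, cfg.allow_neugc_db)
    if proteins is None:
        proteins = random_proteins(rng, cfg.n_proteins)
    db_keys = {t.canonical() for t in glycan_db}
    candidates = _glycopeptide_candidates(proteins)
    if not candidates:
        raise ValueError("no tryptic single-sequon peptides in the proteins")

    false_sources = [t for t in glycan_db if make_false_glycan(t, db_keys) is not None]
    if cfg.n_false > 0 and not false_sources:
        raise ValueError("database supports no isobaric confounders")

    run1: list[Spectrum] = []
    run2: list[Spectrum] = []
    rows: list[dict] = []
    n_total = cfg.n_glycopeptides + cfg.n_weak + cfg.n_false
    for i in range(n_total):
        is_weak = cfg.n_glycopeptides <= i < cfg.n_glycopeptides + cfg.n_weak
        is_false = i >= cfg.n_glycopeptides + cfg.n_weak
        acc, pep, start = candidates[int(rng.integers(0, len(candidates)))]
        if is_false:
            src = false_sources[int(rng.integers(0, len(false_sources)))]
            glycan = make_false_glycan(src, db_keys)
            assert glycan is not None
            confounder_id = src.id
        else:
            glycan = glycan_db[int(rng.integers(0, len(glycan_db)))]
            confounder_id = ""
        j_pos = pep.index("J")
        mods = [(j_pos, MONOSACCHARIDES["HexNAc"])]
        backbone = peptide_neutral_mass(pep)  # unmodified backbone (J itself)
        charge = int(rng.integers(2, 5))
        rt1 = float(rng.uniform(120.0, cfg.gradient_s - 120.0))
        rt2 = rt1 + float(rng.uniform(-cfg.rt_jitter_s, cfg.rt_jitter_s))
        rt2 = min(max(rt2, 0.0), cfg.gradient_s)
        tag = f"plant{i + 1:04d}"
        scale = cfg.weak_pick_scale if is_weak else 1.0
        nmult = cfg.weak_noise_mult if is_weak else 1
        hcd = _ms2_spectrum(
            rng, cfg, "HCD2", f"{tag}.hcd", glycan, backbone, charge, rt1,
            pick_scale=scale, noise_mult=nmult,
        )
        cid = _ms2_spectrum(
            rng, cfg, "CID2", f"{tag}.cid", glycan, backbone, charge, rt1 + 1.0,
            pick_scale=scale, noise_mult=nmult,
        )
        ms3 = _ms3_spectrum(rng, cfg, f"{tag}.ms3", pep, mods, rt2)
        run1.extend([hcd, cid])
        run2.append(ms3)
        rows.append(
            {
                "plant_id": tag,
                "protein": acc,
                "peptide": pep,
                "site": start + j_pos + 1,
                "glycan": glycan.canonical(),
                "glycan_id": glycan.id,
                "composition": str(glycan.composition),
                "backbone_neutral": backbone,
                "charge": charge,
                "rt_run1": rt1,
                "rt_run2": rt2,
                "hcd_title": hcd.title,
                "cid_title": cid.title,
                "ms3_title": ms3.title,
                "label": "false" if is_false else "true",
                "quality": "weak" if is_weak else "strong",
                "confounder_id": confounder_id,
            }
        )

    db_path = out_dir / "glycans.txt"
    fasta_path = out_dir / "proteins.fasta"
    run1_path = out_dir / "run1_hcd_cid.mgf"
    run2_path = out_dir / "run2_ms3.mgf"
    write_glycan_db(glycan_db, db_path)
    from .ms3 import write_fasta

    write_fasta(proteins, fasta_path)
    write_mgf(run1, run1_path)
    write_mgf(run2, run2_path)
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return GroundTruth(
        table=truth,
        glycan_db_path=db_path,
        fasta_path=fasta_path,
        run1_mgf=run1_path,
        run2_mgf=run2_path,
    )
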