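"""Minimal peptide search engine for MS3 spectra of Y1 ions.

An MS3 scan fragments the Y1 ion (peptide + one HexNAc) selected from an
HCD MS2 spectrum, producing b/y ions of the peptide backbone plus
HexNAc neutral-loss (-203.079 Da) forms of fragments carrying the
modified sequon residue.  This module digests a protein FASTA (semi-
tryptic, missed cleavages), substitutes N -> J inside N-glycosylation
sequons (N-X-S/T/C, X != P), enumerates modifications (fixed
carbamidomethyl-C; variable oxidation-M and HexNAc-J), matches b/y
ladders at ion-trap tolerances and controls the PSM FDR with a
concatenated forward/reverse target-decoy search.  Only PSMs carrying a
HexNAc on J — candidate Y1 identities — are accepted.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masses import (
    AA_RESIDUE_MASSES,
    MOD_MASSES,
    PROTON,
    WATER,
    peptide_neutral_mass,
)
from .spectra import Spectrum

__all__ = [
    "DigestParams",
    "ModSpec",
    "Peptide",
    "PSM",
    "read_fasta",
    "write_fasta",
    "sequon_substitute",
    "digest",
    "PeptideIndex",
    "theoretical_ms3_ions",
    "search_ms3",
    "psm_fdr",
]

HEXNAC = MOD_MASSES["HexNAc_J"]


@dataclass(frozen=True)
class DigestParams:
    specificity: str = "semi"  # full | semi
    max_missed: int = 2
    min_length: int = 5
    max_length: int = 40

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.specificity not in {"full", "semi"}:
            raise ValueError("specificity must be 'full' or 'semi'")


@dataclass(frozen=True)
class ModSpec:
    fixed_c: float = MOD_MASSES["carbamidomethyl_C"]
    var_m: float = MOD_MASSES["oxidation_M"]
    var_j: float = MOD_MASSES["HexNAc_J"]
    max_variable: int = 3


@dataclass(frozen=True)
class Peptide:
    sequence: str
    protein: str
    start: int  # 0-based position in the protein
    missed: int
    is_decoy: bool = False


@dataclass
class PSM:
    spectrum_id: str
    peptide: Peptide
    mods: tuple[tuple[int, float], ...]  # (0-based position, delta Da)
    peptide_neutral: float
    charge: int
    n_matched_ions: int
    psm_score: float
    is_decoy: bool
    rt: float = 0.0
    q_value: float = float("nan")

    @property
    def backbone_neutral(self) -> float:
        """Naked peptide backbone mass: the HexNAc on J belongs to the
        glycan (Y1 = backbone + HexNAc), so it is subtracted before
        aligning with MS2-deduced backbone masses."""
        delta = HEXNAC if self.has_hexnac_on_j else 0.0
        return self.peptide_neutral - delta

    @property
    def has_hexnac_on_j(self) -> bool:
        return any(
            self.peptide.sequence[pos] == "J" and abs(delta - HEXNAC) < 1e-6
            for pos, delta in self.mods
        )

    @property
    def modified_sequence(self) -> str:
        out = []
        moddict = dict(self.mods)
        for i, aa in enumerate(self.peptide.sequence):
            out.append(aa)
            if i in moddict:
                out.append(f"[+{moddict[i]:.3f}]")
        return "".join(out)


# ---------------------------------------------------------------------------
# FASTA and digestion
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain multiline FASTA -> {accession: sequence}."""
    proteins: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    proteins[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        proteins[name] = "".join(chunks)
    return proteins


def write_fasta(proteins: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_SEQUON = re.compile(r"N(?=[^P][STC])")


def sequon_substitute(protein_sequence: str) -> str:
    """Replace N with J inside every N-glycosylation sequon.

    The motif is N-X-S/T/C with X != P; overlapping sequons are each
    substituted (lookahead matching).
    """
    return _SEQUON.sub("J", protein_sequence)


def _cleavage_sites(seq: str) -> list[int]:
    """Positions after which trypsin cleaves (after K/R, not before P)."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def digest(
    protein: str,
    p: DigestParams = DigestParams(),
    protein_id: str = "",
    is_decoy: bool = False,
) -> list[Peptide]:
    """In-silico tryptic digestion with missed cleavages.

    Full-specific peptides are spans between cleavage sites with up to
    ``max_missed`` internal sites; semi-specific additionally emits every
    prefix/suffix of those with one ragged terminus.  Deduplicated by
    (sequence, start).
    """
    sites = [0] + _cleavage_sites(protein) + [len(protein)]
    out: dict[tuple[str, int], Peptide] = {}

    def add(start: int, end: int, missed: int) -> None:
        seq = protein[start:end]
        if p.min_length <= len(seq) <= p.max_length:
            out.setdefault(
                (seq, start), Peptide(seq, protein_id, start, missed, is_decoy)
            )

    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + p.max_missed, len(sites))):
            start, end = sites[i], sites[j]
            missed = j - i - 1
            add(start, end, missed)
            if p.specificity == "semi":
                for s in range(start + 1, end):  # N-ragged, tryptic C-terminus
                    add(s, end, missed)
                for e in range(start + 1, end):  # C-ragged, tryptic N-terminus
                    add(start, e, missed)
    return list(out.values())


# ---------------------------------------------------------------------------
# Peptide index with modifications
# ---------------------------------------------------------------------------

def _mod_combinations(
    seq: str, mods: ModSpec
) -> Iterable[tuple[tuple[int, float], ...]]:
    """All fixed+variable modification assignments of one peptide."""
    fixed = tuple((i, mods.fixed_c) for i, aa in enumerate(seq) if aa == "C")
    var_sites: list[tuple[int, float]] = []
    for i, aa in enumerate(seq):
        if aa == "M":
            var_sites.append((i, mods.var_m))
        elif aa == "J":
            var_sites.append((i, mods.var_j))
    for k in range(0, min(mods.max_variable, len(var_sites)) + 1):
        for combo in itertools.combinations(var_sites, k):
            yield fixed + combo


@dataclass
class PeptideIndex:
    """Mass-sorted index of modified peptide forms for precursor lookup."""

    entries: list[tuple[float, Peptide, tuple[tuple[int, float], ...]]] = field(
        default_factory=list
    )
    _masses: np.ndarray | None = None

    @classmethod
    def build(
        cls,
        proteins: dict[str, str],
        digest_params: DigestParams = DigestParams(),
        mods: ModSpec = ModSpec(),
        with_decoys: bool = True,
    ) -> "PeptideIndex":
        """Digest sequon-substituted proteins (and reversed decoys).

        Decoys are reversed protein sequences with the sequon
        substitution re-applied after reversal, so decoy peptides carry
        comparable modifiable-site statistics.
        """
        entries = []
        seen: set[tuple[str, tuple, bool]] = set()
        sources: list[tuple[str, str, bool]] = []
        for acc, seq in proteins.items():
            sources.append((acc, sequon_substitute(seq), False))
        if with_decoys:
            for acc, seq in proteins.items():
                sources.append((f"REV_{acc}", sequon_substitute(seq[::-1]), True))
        for acc, seq, is_decoy in sources:
            for pep in digest(seq, digest_params, protein_id=acc, is_decoy=is_decoy):
                for mod in _mod_combinations(pep.sequence, mods):
                    key = (pep.sequence, mod, is_decoy)
                    if key in seen:
                        continue
                    seen.add(key)
                    mass = peptide_neutral_mass(pep.sequence, mod)
                    entries.append((mass, pep, mod))
        entries.sort(key=lambda e: e[0])
        idx = cls(entries=entries)
        idx._masses = np.asarray([e[0] for e in entries])
        return idx

    def lookup(self, neutral: float, tol_da: float):
        if self._masses is None:
            self._masses = np.asarray([e[0] for e in self.entries])
        lo = int(np.searchsorted(self._masses, neutral - tol_da))
        hi = int(np.searchsorted(self._masses, neutral + tol_da))
        return self.entries[lo:hi]


# ---------------------------------------------------------------------------
# MS3 matching
# ---------------------------------------------------------------------------

def theoretical_ms3_ions(
    sequence: str, mods: Sequence[tuple[int, float]]
) -> list[tuple[float, str]]:
    """Singly-charged b/y m/z values, plus HexNAc neutral-loss forms.

    Fragments that contain a HexNAc-modified J additionally produce the
    -203.079 Da loss ion (the glycosidic bond is the weakest link even in
    MS3).  Returns (m/z, label) pairs.
    """
    n = len(sequence)
    moddict = dict(mods)
    deltas = [moddict.get(i, 0.0) for i in range(n)]
    residue = [AA_RESIDUE_MASSES[aa] + deltas[i] for i, aa in enumerate(sequence)]
    hexnac_at = {
        i
        for i, aa in enumerate(sequence)
        if aa == "J" and abs(moddict.get(i, 0.0) - HEXNAC) < 1e-6
    }
    ions: list[tuple[float, str]] = []
    prefix = 0.0
    for i in range(n - 1):
        prefix += residue[i]
        b = prefix + PROTON
        ions.append((b, f"b{i + 1}"))
        if hexnac_at & set(range(i + 1)):
            ions.append((b - HEXNAC, f"b{i + 1}-HexNAc"))
    suffix = 0.0
    for i in range(n - 1, 0, -1):
        suffix += residue[i]
        y = suffix + WATER + PROTON
        ions.append((y, f"y{n - i}"))
        if hexnac_at & set(range(i, n)):
            ions.append((y - HEXNAC, f"y{n - i}-HexNAc"))
    return ions


def _score_ms3(
    spectrum: Spectrum, ions: list[tuple[float, str]], frag_tol_da: float
) -> tuple[float, int]:
    """Hyperscore-flavoured match score: log-factorial bonus on matched
    b/y counts times log intensity coverage.  Monotone in evidence; the
    absolute scale is irrelevant because acceptance is FDR-calibrated."""
    mzs = spectrum.mz_array
    intens = spectrum.intensity_array
    if mzs.size == 0:
        return 0.0, 0
    base = float(intens.max()) or 1.0
    used: set[int] = set()
    nb = ny = 0
    cover = 0.0
    for mz, label in ions:
        lo = int(np.searchsorted(mzs, mz - frag_tol_da))
        hi = int(np.searchsorted(mzs, mz + frag_tol_da))
        best = -1
        for j in range(lo, hi):
            if j not in used and (best < 0 or intens[j] > intens[best]):
                best = j
        if best < 0:
            continue
        used.add(best)
        cover += intens[best] / base
        if label.startswith("b"):
            nb += 1
        else:
            ny += 1
    if nb + ny == 0:
        return 0.0, 0
    score = (math.lgamma(nb + 1) + math.lgamma(ny + 1) + 1.0) * math.log1p(cover)
    return score, nb + ny


def search_ms3(
    spectrum: Spectrum,
    index: PeptideIndex,
    prec_tol_da: float = 3.0,
    frag_tol_da: float = 0.5,
    charges: Sequence[int] = (1, 2),
) -> list[PSM]:
    """Rank candidate peptides against one MS3 spectrum.

    The MS3 precursor is the Y1 peak selected from the MS2 scan; its
    charge is uncertain, so 1+ and 2+ interpretations are both tried.
    Candidates fall within ±``prec_tol_da`` of the neutral precursor;
    fragments are matched at ±``frag_tol_da`` (ion trap).  Returns PSMs
    sorted by descending score.
    """
    psms: list[PSM] = []
    for z in charges:
        neutral = spectrum.precursor_mz * z - z * PROTON
        for mass, pep, mods in index.lookup(neutral, prec_tol_da):
            ions = theoretical_ms3_ions(pep.sequence, mods)
            score, n_matched = _score_ms3(spectrum, ions, frag_tol_da)
            if n_matched == 0:
                continue
            psms.append(
                PSM(
                    spectrum_id=spectrum.title,
                    peptide=pep,
                    mods=mods,
                    peptide_neutral=mass,
                    charge=z,
                    n_matched_ions=n_matched,
                    psm_score=score,
                    is_decoy=pep.is_decoy,
                    rt=spectrum.retention_time,
                )
            )
    psms.sort(key=lambda p: -p.psm_score)
    return psms


def psm_fdr(psms: Sequence[PSM], q_cut: float = 0.01) -> list[PSM]:
    """Classic target-decoy FDR over best-per-spectrum PSMs.

    FDR(t) = #decoys >= t / #targets >= t; q-values are the running
    minimum.  Accepted PSMs satisfy q <= ``q_cut`` AND carry a HexNAc on
    J (candidate Y1 identities); the HexNAc filter is applied after the
    q-value computation, mirroring a search-engine-level FDR followed by
    the glycopeptide-specific filter.
    """
    ordered = sorted(psms, key=lambda p: -p.psm_score)
    n_t = n_d = 0
    fdrs: list[float] = []
    for p in ordered:
        if p.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(min(1.0, n_d / max(n_t, 1)))
    # q = min FDR over any threshold at least as permissive
    running = 1.0
    qs = [1.0] * len(ordered)
    for i in range(len(ordered) - 1, -1, -1):
        running = min(running, fdrs[i])
        qs[i] = running
    accepted = []
    for p, q in zip(ordered, qs):
        p.q_value = q
        if (not p.is_decoy) and q <= q_cut and p.has_hexnac_on_j:
            accepted.append(p)
    return accepted
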