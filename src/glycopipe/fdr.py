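"""Glycan-level FDR: spectrum-based decoys and a finite mixture model.

Sequence-style decoys are hard to define for glycan trees, so the decoy
is built in spectrum space: the theoretical Y-ion masses of each
candidate are perturbed (a random +U[1, 30] Da per ion by default; a
fixed +11 Da and mass-reversal variants are provided for comparison) and
the decoy spectrum competes against the target under the identical
scoring function.  Because decoy and incorrect-target scores need not be
exchangeable, the naive decoy-count estimate can be biased; a
two-component finite mixture model (FMM) fit by EM on transformed target
scores — the incorrect component anchored on the decoy score
distribution — deconvolves correct from incorrect matches, and the FDR
at a score threshold t is

    FDR(t) = pi0 * S_incorrect(t) / S_mixture(t)

with S a survival function and pi0 the incorrect fraction among targets.
q-values are the running minimum of FDR over thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .glycan_search import (
    GSM,
    IonSpec,
    ScoringParams,
    deduce_backbone,
    filter_y1,
    glycan_ion_offsets,
    match_ions,
    score_glycan,
    _score_from_matches,
)
from .glycans import GlycanTree
from .spectra import SpectrumPair

__all__ = [
    "DecoyConfig",
    "MixtureFit",
    "make_decoy_ions",
    "decoy_ion_specs",
    "competitive_search",
    "search_pair_with_decoy",
    "fit_fmm",
    "estimate_fdr",
    "assign_q_values",
]

DecoyMethod = Literal["random_shift_1_30", "fixed_shift_11", "reverse"]


@dataclass(frozen=True)
class DecoyConfig:
    method: DecoyMethod = "random_shift_1_30"
    rng_seed: int = 0
    decoys_per_target: int = 1
    shift_y0: bool = True  # shift Y0 like every other deduced Y ion
    integer_shifts: bool = False

    def rng_for(self, key: str) -> np.random.Generator:
        """Deterministic per-candidate stream so decoys are reproducible
        regardless of search order."""
        ss = np.random.SeedSequence(
            [self.rng_seed, abs(hash(key)) % (2**31)]
        )
        return np.random.default_rng(ss)


def make_decoy_ions(
    target_masses: Sequence[float],
    cfg: DecoyConfig,
    total_glycan_mass: float,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Perturb target Y glycan-part masses into decoy masses.

    random_shift_1_30: + i.i.d. U(1, 30) Da per ion; fixed_shift_11:
    + 11 Da each; reverse: total glycan mass minus each mass.  With
    ``shift_y0`` false, a zero mass (the naked peptide) is left in place.
    """
    masses = list(target_masses)
    if cfg.method == "reverse":
        out = [total_glycan_mass - m for m in masses]
    elif cfg.method == "fixed_shift_11":
        out = [m + 11.0 for m in masses]
    elif cfg.method == "random_shift_1_30":
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        shifts = rng.uniform(1.0, 30.0, size=len(masses))
        if cfg.integer_shifts:
            shifts = np.floor(shifts)
        out = [m + s for m, s in zip(masses, shifts)]
    else:  # pragma: no cover
        raise ValueError(f"unknown decoy method {cfg.method!r}")
    if not cfg.shift_y0:
        out = [t if abs(m) > 1e-9 else m for m, t in zip(masses, out)]
    return out


def decoy_ion_specs(
    ions: Sequence[IonSpec], cfg: DecoyConfig, total_glycan_mass: float, key: str
) -> list[IonSpec]:
    """Decoy counterpart of a glycan's theoretical ion-offset list."""
    rng = cfg.rng_for(key) if cfg.method == "random_shift_1_30" else None
    masses = make_decoy_ions(
        [i.offset for i in ions], cfg, total_glycan_mass, rng=rng
    )
    return [replace(i, offset=m) for i, m in zip(ions, masses) if m >= 0]


def competitive_search(
    pair: SpectrumPair,
    glycan: GlycanTree,
    backbone: float,
    cfg: DecoyConfig,
    params: ScoringParams | None = None,
) -> tuple[GSM, GSM]:
    """Score one candidate's target and decoy ion sets against a pair.

    The decoy uses the identical scoring function on the perturbed ion
    masses; the caller keeps whichever scores higher.
    """
    params = params or ScoringParams()
    ions = glycan_ion_offsets(glycan)
    target = score_glycan(pair, glycan, backbone, params, offsets=ions)
    key = f"{pair.pair_id}|{glycan.canonical()}"
    dions = decoy_ion_specs(ions, cfg, glycan.mass, key)
    decoy = score_glycan(
        pair, glycan, backbone, params, offsets=dions, is_decoy=True
    )
    return target, decoy


def search_pair_with_decoy(
    pair: SpectrumPair,
    db: Sequence[GlycanTree],
    cfg: DecoyConfig,
    params: ScoringParams | None = None,
) -> tuple[GSM | None, float, float]:
    """Competitive target-decoy search of one spectrum pair.

    Every database glycan that passes the Y1 filter is scored both as
    target and as decoy; the pair's reported GSM is the single best
    scorer, carrying ``is_decoy``.  Also returns the best target and best
    decoy scores of the pair (inputs to the mixture fit).
    """
    params = params or ScoringParams()
    best: tuple[float, int, int, GSM] | None = None
    best_target = 0.0
    best_decoy = 0.0
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
        if score > 0:
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
            best_target = max(best_target, score)
            cand = (-score, -n_core, db_idx, gsm)
            if best is None or cand[:3] < best[:3]:
                best = cand
        key = f"{pair.pair_id}|{glycan.canonical()}"
        dions = decoy_ion_specs(ions, cfg, glycan.mass, key)
        dmatches = match_ions(pair, backbone, dions, params)
        dscore, dn_core = _score_from_matches(pair, dmatches, dions, params)
        if dscore > 0:
            dgsm = GSM(
                pair_id=pair.pair_id,
                glycan=glycan,
                composition=glycan.composition,
                backbone_neutral=backbone,
                score=dscore,
                matched=dmatches,
                n_core_matched=dn_core,
                is_decoy=True,
                rt=pair.retention_time,
                precursor_neutral=pair.precursor_neutral,
            )
            best_decoy = max(best_decoy, dscore)
            cand = (-dscore, -dn_core, db_idx, dgsm)
            if best is None or cand[:3] < best[:3]:
                best = cand
    return (best[3] if best else None), best_target, best_decoy


# ---------------------------------------------------------------------------
# Finite mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Two-component mixture on log1p-transformed scores.

    Incorrect component: location-shifted Gamma with the shape anchored
    on the decoy scores; correct component: Gaussian.  pi0 is the
    incorrect fraction among targets.
    """

    pi0: float
    gamma_shape: float
    gamma_loc: float
    gamma_scale: float
    norm_mu: float
    norm_sigma: float
    #: fraction of decoys with a nonzero score; the zero-score mass (a
    #: decoy that matched nothing) is modelled as a point mass at zero
    #: that no positive threshold can survive
    positive_fraction: float = 1.0
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def _incorrect(self):
        return stats.gamma(self.gamma_shape, loc=self.gamma_loc, scale=self.gamma_scale)

    def _correct(self):
        return stats.norm(self.norm_mu, self.norm_sigma)

    @staticmethod
    def transform(scores: np.ndarray) -> np.ndarray:
        return np.log1p(np.asarray(scores, dtype=float))

    def survival_incorrect(self, score: float) -> float:
        x = np.log1p(score)
        sf = float(self._incorrect().sf(x))
        return self.positive_fraction * sf if x > 0 else 1.0

    def survival_mixture(self, score: float) -> float:
        x = np.log1p(score)
        return float(
            self.pi0 * self.survival_incorrect(score)
            + (1.0 - self.pi0) * self._correct().sf(x)
        )


def _free_two_gaussian_pi0(
    t: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> float:
    """Adaptive pi0: unconstrained two-Gaussian EM on target scores.

    The decoy anchor alone can miss incorrect matches that score far
    above the decoys (coherent wrong-glycan matches harvesting real
    peaks), so the incorrect fraction is additionally estimated from the
    target distribution itself.  A BIC comparison against a single
    Gaussian guards against splitting a clean unimodal score population;
    returns 0 when one component explains the data better.
    """
    lo, hi = np.quantile(t, [0.15, 0.7])
    mu = np.array([lo, hi])
    sigma = np.array([max(t.std() / 2, 1e-2)] * 2)
    w = np.array([0.3, 0.7])
    ll = -np.inf
    for _ in range(max_iter):
        dens = np.stack(
            [w[k] * stats.norm.pdf(t, mu[k], sigma[k]) for k in range(2)]
        )
        mix = np.maximum(dens.sum(axis=0), 1e-300)
        new_ll = float(np.log(mix).sum())
        r = dens / mix
        wk = r.sum(axis=1)
        w = wk / t.size
        for k in range(2):
            if wk[k] > 1e-9:
                mu[k] = (r[k] * t).sum() / wk[k]
                sigma[k] = max(
                    np.sqrt((r[k] * (t - mu[k]) ** 2).sum() / wk[k]), 1e-2
                )
        if abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    # single-Gaussian reference
    ll1 = float(stats.norm.logpdf(t, t.mean(), max(t.std(), 1e-2)).sum())
    bic2 = -2 * ll + 5 * np.log(t.size)
    bic1 = -2 * ll1 + 2 * np.log(t.size)
    if bic2 >= bic1:
        return 0.0
    low = int(np.argmin(mu))  # lower-mean component = incorrect
    return float(np.clip(w[low], 0.0, 1.0))


def fit_fmm(
    target_scores: Sequence[float],
    decoy_scores: Sequence[float],
    min_scores: int = 50,
    max_iter: int = 500,
    tol: float = 1e-6,
    pi0_init: float = 0.5,
) -> MixtureFit:
    """EM fit of the two-component score mixture.

    The Gamma (incorrect) component is fixed from a fit to the decoy
    scores; EM over the target scores updates pi0 and the Gaussian
    correct component (exact M-steps, so the log-likelihood is
    non-decreasing).  pi0 is then floored by the adaptive estimate of
    :func:`_free_two_gaussian_pi0`, which can see incorrect matches that
    score far above the decoy distribution.
    """
    t = MixtureFit.transform(np.asarray(target_scores, dtype=float))
    d = MixtureFit.transform(np.asarray(decoy_scores, dtype=float))
    if t.size < min_scores or d.size < min_scores:
        raise ValueError(
            f"need at least {min_scores} target and decoy scores "
            f"(got {t.size}, {d.size})"
        )
    if np.ptp(t) < 1e-12:
        raise ValueError("degenerate score distribution (all target scores equal)")
    # The incorrect component is the decoy score distribution: a point
    # mass at zero (decoys that matched nothing) plus a Gamma fit to the
    # POSITIVE decoy scores, held FIXED during EM.  This is what lets the
    # decoy construction drive the FDR estimate; EM over the targets then
    # only deconvolves pi0 and the correct (Gaussian) component.  The
    # location sits slightly below the smallest positive decoy to avoid
    # the shape<1 pdf singularity at the boundary.
    d_pos = d[d > 1e-9]
    p_pos = float(d_pos.size / d.size)
    if d_pos.size < 10 or np.ptp(d_pos) < 1e-12:
        # essentially no decoy signal: spike just above zero
        loc, shape, scale = -0.05, 1.0, 1e-3
    else:
        loc = float(d_pos.min()) - 0.05
        shape, _, scale = stats.gamma.fit(d_pos, floc=loc)
        shape = float(np.clip(shape, 0.05, 1e3))
        scale = float(max(scale, 1e-6))
    pi0 = float(np.clip(pi0_init, 1e-3, 1 - 1e-3))
    # correct component initialised from the upper tail of the targets
    hi = t[t >= np.quantile(t, 0.5)]
    mu = float(hi.mean())
    sigma = float(max(hi.std(), 1e-3))
    f0 = np.maximum(
        p_pos * stats.gamma.pdf(t, shape, loc=loc, scale=scale), 1e-300
    )
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        f1 = stats.norm.pdf(t, mu, sigma)
        mix = pi0 * f0 + (1 - pi0) * f1
        mix = np.maximum(mix, 1e-300)
        ll = float(np.log(mix).sum())
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        r0 = pi0 * f0 / mix  # responsibility of the incorrect component
        r1 = 1.0 - r0
        w1 = r1.sum()
        pi0 = float(np.clip(r0.sum() / t.size, 1e-6, 1 - 1e-6))
        if w1 > 1e-9:
            mu = float((r1 * t).sum() / w1)
            sigma = float(max(np.sqrt((r1 * (t - mu) ** 2).sum() / w1), 1e-3))
    pi0 = max(pi0, _free_two_gaussian_pi0(t))
    return MixtureFit(
        pi0=pi0,
        gamma_shape=shape,
        gamma_loc=loc,
        gamma_scale=scale,
        norm_mu=mu,
        norm_sigma=sigma,
        positive_fraction=p_pos,
        loglik_trace=trace,
        converged=converged,
    )


def counting_q_values(gsms: Sequence[GSM]) -> list[GSM]:
    """Classical competitive target-decoy q-values (no mixture model).

    FDR(t) = #decoy GSMs >= t / #target GSMs >= t over the reported
    (competition-winning) GSMs; q is the running minimum.  Used when too
    few scores are available to fit the mixture model.
    """
    ordered = sorted(gsms, key=lambda g: -g.score)
    n_t = n_d = 0
    fdrs = []
    for g in ordered:
        if g.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(min(1.0, n_d / max(n_t, 1)))
    running = 1.0
    qs = [1.0] * len(ordered)
    for i in range(len(ordered) - 1, -1, -1):
        running = min(running, fdrs[i])
        qs[i] = running
    targets = []
    for g, q in zip(ordered, qs):
        if not g.is_decoy:
            g.q_value = q
            targets.append(g)
    return targets


def estimate_fdr(fit: MixtureFit, threshold: float) -> float:
    """Model-based FDR of accepting target GSMs with score >= threshold."""
    s_mix = fit.survival_mixture(threshold)
    if s_mix <= 0:
        return 0.0  # threshold above all scores: nothing accepted
    fdr = fit.pi0 * fit.survival_incorrect(threshold) / s_mix
    return float(np.clip(fdr, 0.0, 1.0))


def assign_q_values(gsms: Sequence[GSM], fit: MixtureFit) -> list[GSM]:
    """Attach q-values (running minimum of FDR over score cutoffs).

    Only target GSMs receive q-values; decoy GSMs keep q = NaN.  Returns
    the target GSMs sorted by descending score.
    """
    targets = sorted(
        (g for g in gsms if not g.is_decoy), key=lambda g: -g.score
    )
    running = 1.0
    fdrs = [estimate_fdr(fit, g.score) for g in targets]
    # scan from the lowest score up so q(s) = min_{t <= s} FDR(t)
    qs = [0.0] * len(targets)
    for i in range(len(targets) - 1, -1, -1):
        running = min(running, fdrs[i])
        qs[i] = running
    for g, q in zip(targets, qs):
        g.q_value = q
    return targets
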