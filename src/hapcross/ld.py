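"""Two-locus linkage disequilibrium: EM haplotype frequencies and
confidence-interval D'.

The pairwise classification follows the confidence-bound block-building
rule: 95% bounds on D' are computed from the profile multinomial likelihood
on a D' grid, and each pair is called strong LD (upper bound > 0.98 and
lower bound > 0.7), strong recombination (upper bound < 0.90) or
inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING

__all__ = ["PairLD", "DegeneratePairError", "em_haplotype_freqs", "dprime_ci",
           "pair_ld"]

#: default classification bounds
STRONG_LD_HIGH = 0.98
STRONG_LD_LOW = 0.70
RECOMB_HIGH = 0.90


class DegeneratePairError(ValueError):
    """A locus pair where D' is undefined (a monomorphic locus)."""


@dataclass
class PairLD:
    """LD summary for one marker pair.

    Haplotype labels: ``A``/``B`` are the dosage-0 alleles at the two loci,
    so ``p_ab`` is the frequency of the double dosage-2 haplotype.
    """

    p_ab_freqs: tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    d: float
    d_prime: float
    ci_low: float
    ci_high: float
    classification: str  # strong_LD | strong_recombination | inconclusive
    n_gametes: int
    low_information: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.p_ab_freqs, dtype=float)
        if (f < -1e-9).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be >= 0 and sum to 1")
        if self.ci_low > self.ci_high + 1e-12:
            raise ValueError("CI low must not exceed CI high")


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, float, float]:
    """Maximum-likelihood two-locus haplotype frequencies from unphased calls.

    Phase-known configurations are counted directly; double heterozygotes
    are split between the coupling and repulsion phases by EM, iterated to
    ``|delta| < tol`` or ``max_iter`` sweeps.  Returns
    ``(p_AB, p_Ab, p_aB, p_ab)`` with A/B the dosage-0 alleles.

    Missing calls at either locus drop the line (listwise per pair).
    """
    freqs, _, _ = _em_full(g1, g2, tol, max_iter)
    return tuple(freqs)


def _em_full(g1, g2, tol=1e-8, max_iter=1000):
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    n_lines = g1.size
    if n_lines == 0:
        raise DegeneratePairError("no pairwise-complete lines")
    # counts of the A allele (dosage 0) per line
    a1 = 2 - g1.astype(int)
    a2 = 2 - g2.astype(int)
    # fixed haplotype counts from phase-known individuals
    dh = (g1 == 1) & (g2 == 1)
    n_dh = int(dh.sum())
    # 9 diploid categories (A-allele counts 0/1/2 at each locus) -> fixed
    # haplotype contributions; the double-het category (1,1) stays zero
    table = np.zeros((9, 4))
    for c1 in (0, 1, 2):
        for c2 in (0, 1, 2):
            if c1 == 1 and c2 == 1:
                continue
            row = table[c1 * 3 + c2]
            if c1 != 1 and c2 != 1:
                row[(1 - c1 // 2) * 2 + (1 - c2 // 2)] += 2
            elif c1 == 1:  # locus 1 het, locus 2 homozygous
                j = 1 - c2 // 2
                row[j] += 1       # A_
                row[2 + j] += 1   # a_
            else:          # locus 2 het, locus 1 homozygous
                i = 1 - c1 // 2
                row[i * 2] += 1
                row[i * 2 + 1] += 1
    cat = np.bincount((a1 * 3 + a2)[~dh], minlength=9)
    counts = table.T @ cat
    n_gam = 2 * n_lines
    if n_dh == 0:
        freqs = counts / n_gam
        return freqs, n_gam, False
    # EM over the double-het phase split
    freqs = np.full(4, 0.25)
    known = counts.copy()
    for _ in range(max_iter):
        coup = freqs[0] * freqs[3]
        rep = freqs[1] * freqs[2]
        w = coup / (coup + rep) if coup + rep > 0 else 0.5
        new = known.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= n_gam
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    low_info = n_dh == n_lines
    return freqs, n_gam, low_info


def _dmax(p_a: float, p_b: float, d: float) -> float:
    qa, qb = 1.0 - p_a, 1.0 - p_b
    if d > 0:
        return min(p_a * qb, qa * p_b)
    return min(p_a * p_b, qa * qb)


def dprime_ci(
    freqs,
    n_gametes: int,
    strong_ld_high: float = STRONG_LD_HIGH,
    strong_ld_low: float = STRONG_LD_LOW,
    recomb_high: float = RECOMB_HIGH,
    grid_points: int = 101,
    low_information: bool = False,
) -> PairLD:
    """D', its 95% likelihood-based confidence bounds, and the pairwise call.

    D = p_AB - p_A p_B; D' = |D| / Dmax.  The bounds come from the profile
    multinomial likelihood over a ``grid_points``-point D' grid in [0, 1]
    (allele frequencies held at their estimates): the likelihood mass is
    normalized and the 5th/95th percentiles of its cumulative distribution
    are reported.  Classification: strong LD iff upper > ``strong_ld_high``
    and lower > ``strong_ld_low``; strong recombination iff upper <
    ``recomb_high``; otherwise inconclusive.
    """
    if n_gametes < 2:
        raise ValueError("need at least 2 gametes")
    f = np.asarray(freqs, dtype=float)
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    d = f[0] - p_a * p_b
    dmax = _dmax(p_a, p_b, d if d != 0 else 1.0)
    if dmax <= 0:
        raise DegeneratePairError(
            f"monomorphic locus (p_A={p_a:.3f}, p_B={p_b:.3f})")
    d_prime = min(abs(d) / dmax, 1.0)
    sign = 1.0 if d >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    obs = f * n_gametes  # (possibly fractional) gamete counts
    loglik = np.empty(grid_points)
    qa, qb = 1.0 - p_a, 1.0 - p_b
    base = np.array([p_a * p_b, p_a * qb, qa * p_b, qa * qb])
    delta = sign * np.array([1.0, -1.0, -1.0, 1.0]) * dmax
    for i, g in enumerate(grid):
        probs = np.clip(base + g * delta, 1e-12, None)
        probs /= probs.sum()
        loglik[i] = float(obs @ np.log(probs))
    lik = np.exp(loglik - loglik.max())
    cdf = np.cumsum(lik) / lik.sum()
    ci_low = float(grid[int(np.searchsorted(cdf, 0.05))])
    hi_idx = int(np.searchsorted(cdf, 0.95))
    ci_high = float(grid[min(hi_idx, grid_points - 1)])
    if ci_high > strong_ld_high and ci_low > strong_ld_low:
        classification = "strong_LD"
    elif ci_high < recomb_high:
        classification = "strong_recombination"
    else:
        classification = "inconclusive"
    if low_information:
        classification = "inconclusive"
    return PairLD(tuple(f), float(d), float(d_prime), ci_low, ci_high,
                  classification, int(n_gametes), low_information)


def pair_ld(g1: np.ndarray, g2: np.ndarray, **kwargs) -> PairLD:
    """EM frequencies + CI D' for one marker pair of dosage vectors."""
    freqs, n_gam, low_info = _em_full(g1, g2)
    return dprime_ci(freqs, n_gam, low_information=low_info, **kwargs)
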