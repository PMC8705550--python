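"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies are estimated by the classic expectation-maximisation
(EM) algorithm over the 3x3 joint genotype table: every genotype pair except
the double heterozygote resolves unambiguously into two gametes; the double
heterozygote is split between the cis (AB/ab) and trans (Ab/aB) phases in
proportion to their current expected frequencies, assuming random union of
gametes. From the converged haplotype frequencies the standard pairwise
statistics follow:

    D  = p_AB - p_A p_B
    D' = D / D_max
    r2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B))

together with the coupled-allele phase: the allele of the second variant
that preferentially rides on the same haplotype as a given allele of the
first (the sign of D). The coupling is what lets a disease risk allele be
carried over to a molecular-QTL effect allele observed at a proxy variant.

Numerical contract
------------------
* EM starts at linkage equilibrium (product of observed allele
  frequencies); the start is deterministic, so results carry no seed.
* Convergence: max absolute frequency change < 1e-10, or 1000 iterations.
* Monomorphic loci make every LD statistic undefined; this is signalled by
  ``undefined=True`` on the result, never by an exception.
* An exactly phase-symmetric solution (cis and trans products equal while
  double heterozygotes are present) cannot orient the coupling; it is
  flagged ``degenerate=True`` and downstream direction calling refuses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_model import GenotypePanel, GwasHit, Variant, MISSING_GENOTYPE

__all__ = ["EMResult", "LDPair", "em_haplotype_freqs", "ld_pair", "expand_proxies"]

EM_TOL = 1e-10
EM_MAX_ITER = 1000
_PHASE_TOL = 1e-9

#: default proxy search window around an index variant, in base pairs
DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class EMResult:
    """Converged two-locus haplotype frequencies.

    ``freqs[i, j]`` is the frequency of the haplotype carrying allele *i*
    at the first locus and allele *j* at the second, where index 1 denotes
    the counted (``allele_b``) allele and index 0 the other allele.
    """

    freqs: np.ndarray  # shape (2, 2)
    n_iter: int
    converged: bool
    log_likelihood: float
    undefined: bool = False
    degenerate: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def p_a(self) -> float:
        """Frequency of the counted allele at the first locus."""
        return float(self.freqs[1, 0] + self.freqs[1, 1])

    @property
    def p_b(self) -> float:
        """Frequency of the counted allele at the second locus."""
        return float(self.freqs[0, 1] + self.freqs[1, 1])


@dataclass
class LDPair:
    """Pairwise LD between two variants, with the coupled-allele phase.

    ``coupled`` maps each allele of ``var_a`` to the allele of ``var_b``
    that co-occurs with it in positive LD (a bijection on the two alleles).
    It is ``None`` when the pair is undefined or phase-degenerate.
    """

    var_a: Variant
    var_b: Variant
    r2: float
    d: float
    d_prime: float
    coupled: Optional[Mapping[str, str]]
    n_eff: int
    undefined: bool = False
    degenerate: bool = False


def _genotype_table(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, int]:
    """Joint 3x3 genotype counts with pairwise deletion of missing calls."""
    keep = (ga != MISSING_GENOTYPE) & (gb != MISSING_GENOTYPE)
    ga, gb = ga[keep], gb[keep]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (ga.astype(np.intp), gb.astype(np.intp)), 1)
    return counts, int(keep.sum())


def _loglik(freqs: np.ndarray, n: np.ndarray) -> float:
    p11, p10 = freqs[1, 1], freqs[1, 0]
    p01, p00 = freqs[0, 1], freqs[0, 0]
    probs = np.array(
        [
            [p00**2, 2 * p00 * p01, p01**2],
            [2 * p00 * p10, 2 * (p11 * p00 + p10 * p01), 2 * p01 * p11],
            [p10**2, 2 * p10 * p11, p11**2],
        ]
    )
    with np.errstate(divide="ignore"):
        terms = np.where(n > 0, n * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(terms.sum())


def em_haplotype_freqs(
    genotype_counts: Sequence[Sequence[int]] | np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> EMResult:
    """Estimate two-locus haplotype frequencies from a 3x3 genotype table.

    Parameters
    ----------
    genotype_counts
        ``genotype_counts[i][j]`` = number of samples carrying *i* copies of
        the counted allele at the first locus and *j* copies at the second
        (i, j in 0..2). Counts must be non-negative with a positive total.

    Returns
    -------
    EMResult
        Converged frequencies (summing to 1), the log-likelihood and the
        per-iteration trace, plus ``undefined``/``degenerate`` flags.
    """
    n = np.asarray(genotype_counts, dtype=float)
    if n.shape != (3, 3):
        raise ValueError(f"genotype_counts must be 3x3, got shape {n.shape}")
    if (n < 0).any():
        raise ValueError("genotype counts must be non-negative")
    total = n.sum()
    if total < 1:
        raise ValueError("genotype counts must total at least 1")

    two_n = 2.0 * total
    # observed allele frequencies (fixed points of the EM update)
    p_a = (2 * n[2, :].sum() + n[1, :].sum()) / two_n
    p_b = (2 * n[:, 2].sum() + n[:, 1].sum()) / two_n

    freqs = np.array(
        [
            [(1 - p_a) * (1 - p_b), (1 - p_a) * p_b],
            [p_a * (1 - p_b), p_a * p_b],
        ]
    )
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return EMResult(
            freqs=freqs,
            n_iter=0,
            converged=True,
            log_likelihood=_loglik(freqs, n),
            undefined=True,
            loglik_trace=[_loglik(freqs, n)],
        )

    n11 = n[1, 1]
    # gamete counts fixed by unambiguous genotypes
    base11 = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    base10 = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    base01 = 2 * n[0, 2] + n[1, 2] + n[0, 1]
    base00 = 2 * n[0, 0] + n[1, 0] + n[0, 1]

    trace = [_loglik(freqs, n)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = freqs[1, 1] * freqs[0, 0]
        trans = freqs[1, 0] * freqs[0, 1]
        denom = cis + trans
        x = n11 * (cis / denom) if denom > 0 else 0.5 * n11
        new = np.array(
            [
                [(base00 + x) / two_n, (base01 + n11 - x) / two_n],
                [(base10 + n11 - x) / two_n, (base11 + x) / two_n],
            ]
        )
        delta = np.abs(new - freqs).max()
        freqs = new
        trace.append(_loglik(freqs, n))
        if delta < tol:
            converged = True
            break

    cis = freqs[1, 1] * freqs[0, 0]
    trans = freqs[1, 0] * freqs[0, 1]
    degenerate = n11 > 0 and abs(cis - trans) < _PHASE_TOL
    return EMResult(
        freqs=freqs,
        n_iter=it,
        converged=converged,
        log_likelihood=trace[-1],
        degenerate=degenerate,
        loglik_trace=trace,
    )


def ld_from_freqs(em: EMResult) -> tuple[float, float, float]:
    """(D, D', r2) for the counted alleles, from converged frequencies."""
    p_a, p_b = em.p_a, em.p_b
    d = float(em.freqs[1, 1] - p_a * p_b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return d, 0.0, float("nan")
    r2 = d * d / denom
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0
    d_prime = d / d_max if d_max > 0 else 0.0
    return d, d_prime, r2


def ld_pair(panel: GenotypePanel, var_a: Variant, var_b: Variant) -> LDPair:
    """Pairwise LD between two panel variants from unphased genotypes.

    Samples missing a genotype at either locus are excluded pairwise; the
    retained count is reported as ``n_eff``. The ``coupled`` mapping sends
    each allele of ``var_a`` to its positive-LD partner allele of ``var_b``.
    """
    ia, ib = panel.index_of(var_a), panel.index_of(var_b)
    pa, pb = panel.variants[ia], panel.variants[ib]
    counts, n_eff = _genotype_table(panel.genotypes[ia], panel.genotypes[ib])
    if n_eff == 0:
        return LDPair(
            var_a=pa, var_b=pb, r2=float("nan"), d=float("nan"), d_prime=float("nan"),
            coupled=None, n_eff=0, undefined=True,
        )
    em = em_haplotype_freqs(counts)
    d, d_prime, r2 = ld_from_freqs(em)
    if em.undefined or em.degenerate or d == 0:
        return LDPair(
            var_a=pa, var_b=pb,
            r2=float("nan") if em.undefined else r2,
            d=d, d_prime=d_prime, coupled=None, n_eff=n_eff,
            undefined=em.undefined,
            degenerate=not em.undefined,
        )
    if d > 0:
        coupled = {pa.allele_b: pb.allele_b, pa.allele_a: pb.allele_a}
    else:
        coupled = {pa.allele_b: pb.allele_a, pa.allele_a: pb.allele_b}
    return LDPair(
        var_a=pa, var_b=pb, r2=r2, d=d, d_prime=d_prime, coupled=coupled, n_eff=n_eff
    )


def expand_proxies(
    panel: GenotypePanel,
    hits: Sequence[GwasHit],
    r2_min: float = 0.7,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> dict[GwasHit, list[tuple[Variant, float]]]:
    """Expand each index variant to its LD proxies in the reference panel.

    Every hit maps to itself with r2 = 1, plus every panel variant within
    ``window_bp`` whose r2 with the hit strictly exceeds ``r2_min``
    (default 0.7). Proxy lists are sorted by descending r2, ties broken by
    genomic position. A hit absent from the panel keeps only its
    self-proxy, with a warning.
    """
    if not (0 < r2_min <= 1):
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    out: dict[GwasHit, list[tuple[Variant, float]]] = {}
    for hit in hits:
        hv = hit.variant
        proxies: list[tuple[Variant, float]] = [(hv, 1.0)]
        if hv not in panel:
            warnings.warn(
                f"hit {hv.label} absent from reference panel; keeping self-proxy only",
                stacklevel=2,
            )
            out[hit] = proxies
            continue
        for cand in panel.variants:
            if cand.pos_key == hv.pos_key or cand.chrom != hv.chrom:
                continue
            if abs(cand.pos - hv.pos) > window_bp:
                continue
            pair = ld_pair(panel, hv, cand)
            if pair.undefined or not (pair.r2 > r2_min):
                continue
            proxies.append((cand, pair.r2))
        proxies.sort(key=lambda t: (-t[1], t[0].pos))
        out[hit] = proxies
    return out
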