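"""EM haplotype-frequency phasing for small regions.

Enumerates every diplotype compatible with each unphased genotype vector
(missing sites marginalized over both alleles), runs EM on population
haplotype frequencies, and reports per individual the maximum-a-posteriori
diplotype with its posterior under the final frequencies.  Individuals below
a posterior cutoff can then be excluded from haplotype comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, CohortStudy, HaplotypePanel, PipelineError, SiteInfo

MAX_SITES = 25
_MAX_DIPLOTYPES = 1 << 18


class RegionTooWideError(PipelineError):
    """Raised when diplotype enumeration is infeasible; window the region."""


@dataclass
class PhasedIndividual:
    index: int
    hap_pair: tuple[np.ndarray, np.ndarray]
    posterior: float


def _bit_rows(n_bits: int) -> np.ndarray:
    """(2**n_bits, n_bits) matrix of all bit patterns."""
    n = 1 << n_bits
    return ((np.arange(n)[:, None] >> np.arange(n_bits)[None, :]) & 1).astype(np.int8)


def _compatible_diplotype_arrays(genotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All unordered haplotype pairs (A, B) summing to the genotype.

    Heterozygous sites split 0|1 between the pair (the first one is pinned to
    break the pair-swap symmetry); missing sites take any of the four phased
    combinations, deduplicated when no het site orders the pair.
    """
    g = np.asarray(genotype)
    het = np.flatnonzero(g == 1)
    miss = np.flatnonzero(g == MISSING)
    h, m = len(het), len(miss)
    if (1 << max(h - 1, 0)) << (2 * m) > _MAX_DIPLOTYPES:
        raise RegionTooWideError(
            f"{h} het + {m} missing sites: enumeration too large; "
            "phase the region in smaller windows"
        )
    base = np.where(g == 2, 1, 0).astype(np.int8)

    het_a = np.zeros((1, h), np.int8)
    if h > 0:  # first het pinned to allele 0 on haplotype A
        het_a = np.hstack([np.zeros((1 << (h - 1), 1), np.int8), _bit_rows(h - 1)])
    miss_bits = _bit_rows(m)
    nm = miss_bits.shape[0]
    if h > 0:
        ma = np.repeat(np.arange(nm), nm)
        mb = np.tile(np.arange(nm), nm)
    else:  # no het site: order the pair by its missing-site bits instead
        ma, mb = np.triu_indices(nm)
    n_het, n_miss = het_a.shape[0], ma.size
    A = np.repeat(np.tile(base, (n_het, 1)), n_miss, axis=0)
    B = A.copy()
    if h > 0:
        A[:, het] = np.repeat(het_a, n_miss, axis=0)
        B[:, het] = 1 - A[:, het]
    if m > 0:
        A[:, miss] = np.tile(miss_bits[ma], (n_het, 1))
        B[:, miss] = np.tile(miss_bits[mb], (n_het, 1))
    return A, B


def phase_em(
    genotypes: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> tuple[list[PhasedIndividual], dict[tuple[int, ...], float]]:
    """Phase a genotype matrix (individuals x sites) by haplotype-frequency EM.

    Returns phased individuals (MAP diplotype + posterior) and the final
    haplotype frequency estimates.  The EM log-likelihood is asserted to be
    monotone non-decreasing every iteration.
    """
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise ValueError("genotypes must be a matrix")
    n, L = G.shape
    if L > MAX_SITES:
        raise RegionTooWideError(
            f"{L} sites exceeds the {MAX_SITES}-site enumeration limit; "
            "phase the region in smaller windows"
        )
    blocks_a, blocks_b, sizes = [], [], []
    for i in range(n):
        A, B = _compatible_diplotype_arrays(G[i])
        blocks_a.append(A)
        blocks_b.append(B)
        sizes.append(A.shape[0])
    all_rows = np.vstack(blocks_a + blocks_b)
    powers = (np.uint64(1) << np.arange(L, dtype=np.uint64))
    packed = all_rows.astype(np.uint64) @ powers  # L <= 25 fits one word
    uniq_keys, inverse = np.unique(packed, return_inverse=True)
    haps = ((uniq_keys[:, None] >> np.arange(L, dtype=np.uint64)[None, :]) & 1).astype(np.int8)
    H = haps.shape[0]
    P = sum(sizes)
    idx_a, idx_b = inverse[:P], inverse[P:]
    bounds = np.cumsum([0] + sizes)
    ind_pairs = [
        np.column_stack([idx_a[bounds[i]:bounds[i + 1]], idx_b[bounds[i]:bounds[i + 1]]])
        for i in range(n)
    ]

    rng = np.random.default_rng(seed)
    freqs = 1.0 + 1e-3 * rng.random(H)
    freqs /= freqs.sum()

    # flatten diplotype lists for vectorized E steps
    owner = np.concatenate([np.full(len(idx), i) for i, idx in enumerate(ind_pairs)])
    flat = np.vstack(ind_pairs)
    mult = np.where(flat[:, 0] != flat[:, 1], 2.0, 1.0)

    prev_ll = -np.inf
    for _ in range(max_iter):
        w = mult * freqs[flat[:, 0]] * freqs[flat[:, 1]]
        tot = np.bincount(owner, weights=w, minlength=n)
        ll = float(np.log(tot).sum())
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        wn = w / tot[owner]
        counts = np.bincount(flat[:, 0], weights=wn, minlength=H)
        counts += np.bincount(flat[:, 1], weights=wn, minlength=H)
        freqs = counts / (2 * n)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    phased = []
    for i, idx in enumerate(ind_pairs):
        w = freqs[idx[:, 0]] * freqs[idx[:, 1]]
        w = np.where(idx[:, 0] != idx[:, 1], 2.0 * w, w)
        tot = w.sum()
        best = int(np.argmax(w))
        post = float(w[best] / tot) if tot > 0 else 1.0 / len(w)
        phased.append(
            PhasedIndividual(
                index=i,
                hap_pair=(haps[idx[best, 0]].copy(), haps[idx[best, 1]].copy()),
                posterior=post,
            )
        )
    freq_table = {tuple(int(v) for v in haps[k]): float(freqs[k]) for k in range(H) if freqs[k] > 0}
    return phased, freq_table


def filter_phased(
    individuals: list[PhasedIndividual], min_posterior: float = 0.9
) -> tuple[list[PhasedIndividual], int]:
    """Drop individuals whose MAP-diplotype posterior is strictly below the
    cutoff; returns (retained, n_excluded)."""
    retained = [p for p in individuals if p.posterior >= min_posterior]
    return retained, len(individuals) - len(retained)


def phased_panel(
    individuals: list[PhasedIndividual], sites: list[SiteInfo]
) -> HaplotypePanel:
    """Stack phased haplotypes (2 rows per individual) into a panel with
    per-individual provenance labels."""
    if not individuals:
        raise ValueError("no phased individuals to stack")
    alleles = np.vstack([np.vstack(p.hap_pair) for p in individuals])
    labels = [f"ind{p.index}_{h}" for p in individuals for h in (0, 1)]
    return HaplotypePanel(alleles=alleles, sites=list(sites), labels=labels)


def phase_study(
    study: CohortStudy, max_iter: int = 500, tol: float = 1e-8, seed: int = 0
) -> tuple[list[PhasedIndividual], list[PhasedIndividual]]:
    """Phase cases and controls pooled as one group; split the result back."""
    pooled = study.pooled()
    phased, _ = phase_em(pooled, max_iter=max_iter, tol=tol, seed=seed)
    return phased[: study.n_cases], phased[study.n_cases:]
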