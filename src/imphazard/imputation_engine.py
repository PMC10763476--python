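"""Haplotype-copying HMM imputation of masked sites against a phased panel.

Each target haplotype is modelled as a mosaic of the K reference haplotypes.
Between adjacent used sites at distance d kb the chain stays on its state
with probability exp(-rho*d/K) + t/K and jumps to each state with t/K,
where t = 1 - exp(-rho*d/K); emissions match the copied allele with
probability 1 - epsilon.  Sites with no observed target allele (the masked
ones) emit uniformly, so the forward-backward pass yields copying-state
posteriors at masked positions, from which allele posteriors and diploid
genotype probability triples follow.

The implementation collapses duplicated reference haplotypes into weighted
states, which is exact for this uniform-jump transition kernel, and rescales
messages per site; the contract is exactness of posteriors, not likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, CohortStudy, HaplotypePanel, PipelineError


class NotImputableError(PipelineError):
    """Scaffold sites required by the model are absent from the reference."""


def default_epsilon(n_reference_haplotypes: int) -> float:
    """Watterson-style copy-error rate: theta/(2*(K+theta)) with
    theta = 1/sum_{i<K} 1/i."""
    K = n_reference_haplotypes
    if K < 2:
        return 1e-4
    theta = 1.0 / np.sum(1.0 / np.arange(1, K))
    return float(theta / (2.0 * (K + theta)))


@dataclass
class ImputationConfig:
    reference: HaplotypePanel
    rho_per_kb: float = 0.4
    epsilon: float | None = None
    call_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.rho_per_kb < 0:
            raise ValueError("rho_per_kb must be >= 0")
        if not 0.0 < self.call_threshold <= 1.0:
            raise ValueError("call_threshold must be in (0, 1]")
        if self.epsilon is not None and not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")

    @property
    def effective_epsilon(self) -> float:
        if self.epsilon is not None:
            return self.epsilon
        return default_epsilon(self.reference.n_haplotypes)


@dataclass
class PosteriorGenotypes:
    """Per-individual genotype probability triples at masked sites."""

    site_ids: list[str]
    cases: np.ndarray  # (n_cases, M, 3)
    controls: np.ndarray  # (n_controls, M, 3)
    not_imputable: list[str] = field(default_factory=list)

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.cases, self.controls], axis=0)


def _emissions(targets: np.ndarray, ref_alleles: np.ndarray, eps: float) -> np.ndarray:
    """(n_targets, K, L) emission likelihoods; unobserved target alleles
    (MISSING) emit 1 for every state."""
    t = targets[:, None, :]
    r = ref_alleles[None, :, :]
    em = np.where(t == r, 1.0 - eps, eps)
    return np.where(t == MISSING, 1.0, em)


def _stay_probs(pos_bp: np.ndarray, rho_per_kb: float, K: int) -> np.ndarray:
    """exp(-rho*d/K) for each of the L-1 adjacent intervals."""
    d_kb = np.diff(pos_bp.astype(float)) / 1000.0
    return np.exp(-rho_per_kb * d_kb / K)


def _forward_backward(
    targets: np.ndarray,
    ref_alleles: np.ndarray,
    weights: np.ndarray,
    pos_bp: np.ndarray,
    rho_per_kb: float,
    eps: float,
    K_total: int,
    query: np.ndarray,
) -> np.ndarray:
    """Batched scaled forward-backward; returns state posteriors of shape
    (n_targets, len(query), n_states) at the queried site indices.

    ``weights`` is the stationary/jump distribution over the (possibly
    collapsed) states; with unique states carrying their duplicate counts
    this reproduces the uniform kernel over all ``K_total`` haplotypes.
    """
    n, L = targets.shape
    S = ref_alleles.shape[0]
    em = _emissions(targets, ref_alleles, eps)  # (n, S, L)
    stay = _stay_probs(pos_bp, rho_per_kb, K_total)
    qpos = {int(q): k for k, q in enumerate(query)}

    fwd_at_q = np.empty((n, len(query), S))
    f = weights[None, :] * em[:, :, 0]
    f = f / f.sum(axis=1, keepdims=True)
    if 0 in qpos:
        fwd_at_q[:, qpos[0]] = f
    for l in range(1, L):
        r = stay[l - 1]
        f = em[:, :, l] * (r * f + (1.0 - r) * weights[None, :])
        f = f / f.sum(axis=1, keepdims=True)
        if l in qpos:
            fwd_at_q[:, qpos[l]] = f

    bwd_at_q = np.empty((n, len(query), S))
    b = np.ones((n, S))
    if L - 1 in qpos:
        bwd_at_q[:, qpos[L - 1]] = b
    for l in range(L - 2, -1, -1):
        r = stay[l]
        u = em[:, :, l + 1] * b
        b = r * u + (1.0 - r) * (u * weights[None, :]).sum(axis=1, keepdims=True)
        b = b / b.sum(axis=1, keepdims=True)
        if l in qpos:
            bwd_at_q[:, qpos[l]] = b

    gamma = fwd_at_q * bwd_at_q
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma


def copying_posteriors(target_hap: np.ndarray, config: ImputationConfig) -> np.ndarray:
    """Copying-state posteriors over all K reference haplotypes at every
    reference site.

    ``target_hap`` is aligned to ``config.reference.sites`` with MISSING at
    untyped (masked) positions.
    """
    ref = config.reference
    target = np.asarray(target_hap, dtype=np.int8)
    if target.shape != (ref.n_sites,):
        raise ValueError(f"target must have one entry per reference site ({ref.n_sites})")
    K = ref.n_haplotypes
    weights = np.full(K, 1.0 / K)
    gamma = _forward_backward(
        target[None, :],
        ref.alleles,
        weights,
        ref.positions_bp,
        config.rho_per_kb,
        config.effective_epsilon,
        K,
        query=np.arange(ref.n_sites),
    )
    return gamma[0]


def _haploid_alt_posteriors(
    targets: np.ndarray, config: ImputationConfig, query: np.ndarray
) -> np.ndarray:
    """P(allele = alt) at the queried reference sites for each target
    haplotype, via weighted-unique-state forward-backward."""
    ref = config.reference
    K = ref.n_haplotypes
    eps = config.effective_epsilon
    uniq, inverse, counts = np.unique(
        ref.alleles, axis=0, return_inverse=True, return_counts=True
    )
    weights = counts / K
    gamma = _forward_backward(
        targets, uniq, weights, ref.positions_bp, config.rho_per_kb, eps, K, query
    )
    alt = uniq[:, query].T.astype(float)  # (len(query), S)
    p_alt = eps + (1.0 - 2.0 * eps) * np.einsum("nqs,qs->nq", gamma, alt)
    return np.clip(p_alt, 0.0, 1.0)


def impute_masked(
    study: CohortStudy,
    masked_site_ids: list[str],
    config: ImputationConfig,
    scaffold_haps: tuple[np.ndarray, np.ndarray] | None = None,
) -> PosteriorGenotypes:
    """Impute masked sites for every individual from scaffold haplotypes.

    The two haplotypes of each individual are imputed independently
    (haploid copying) and their allele posteriors convolved into genotype
    probability triples.  ``scaffold_haps`` gives (case, control) haplotype
    matrices over the *study* site order, two rows per individual; when
    omitted the study's truth haplotypes are used.  Masked sites absent from
    the reference are reported not-imputable; scaffold sites absent from the
    reference raise :class:`NotImputableError`.
    """
    ref = config.reference
    ref_key = {(s.chrom, s.pos_bp, s.ref_allele, s.alt_allele): i for i, s in enumerate(ref.sites)}

    masked_set = set(masked_site_ids)
    unknown = masked_set - set(study.site_ids)
    if unknown:
        raise ValueError(f"masked sites not in study: {sorted(unknown)}")

    scaffold_study_idx, scaffold_ref_idx, missing_scaffold = [], [], []
    for j, s in enumerate(study.sites):
        if s.id in masked_set:
            continue
        ri = ref_key.get((s.chrom, s.pos_bp, s.ref_allele, s.alt_allele))
        if ri is None:
            missing_scaffold.append(s.id)
        else:
            scaffold_study_idx.append(j)
            scaffold_ref_idx.append(ri)
    if missing_scaffold:
        raise NotImputableError(
            f"scaffold sites absent from reference (alleles must match exactly): {missing_scaffold}"
        )

    sidx = study.site_index()
    imputable, not_imputable, masked_ref_idx = [], [], []
    for sid in masked_site_ids:
        s = study.sites[sidx[sid]]
        ri = ref_key.get((s.chrom, s.pos_bp, s.ref_allele, s.alt_allele))
        if ri is None:
            not_imputable.append(sid)
        else:
            imputable.append(sid)
            masked_ref_idx.append(ri)

    if scaffold_haps is None:
        if study.truth_case_haps is None or study.truth_control_haps is None:
            raise ValueError("no scaffold haplotypes: phase the study or supply truth haplotypes")
        case_h = study.truth_case_haps.alleles
        ctrl_h = study.truth_control_haps.alleles
    else:
        case_h, ctrl_h = (np.asarray(h, dtype=np.int8) for h in scaffold_haps)
        if case_h.shape != (2 * study.n_cases, study.n_sites) or \
           ctrl_h.shape != (2 * study.n_controls, study.n_sites):
            raise ValueError("scaffold haplotype matrices must be (2N x study sites)")

    # restrict the model to scaffold + imputable masked sites, position order
    used_ref_idx = np.array(sorted(set(scaffold_ref_idx) | set(masked_ref_idx)), dtype=np.intp)
    sub_ref = ref.subset_sites(used_ref_idx)
    ref_to_sub = {int(ri): k for k, ri in enumerate(used_ref_idx)}
    query = np.array([ref_to_sub[ri] for ri in masked_ref_idx], dtype=np.intp)

    out = {}
    for group, haps in (("cases", case_h), ("controls", ctrl_h)):
        targets = np.full((haps.shape[0], used_ref_idx.size), MISSING, dtype=np.int8)
        for sj, ri in zip(scaffold_study_idx, scaffold_ref_idx):
            targets[:, ref_to_sub[ri]] = haps[:, sj]
        sub_cfg = ImputationConfig(
            reference=sub_ref,
            rho_per_kb=config.rho_per_kb,
            epsilon=config.effective_epsilon,
            call_threshold=config.call_threshold,
        )
        if query.size:
            p_alt = _haploid_alt_posteriors(targets, sub_cfg, query)  # (2N, M)
            pa, pb = p_alt[0::2], p_alt[1::2]
            triples = np.stack(
                [
                    (1 - pa) * (1 - pb),
                    pa * (1 - pb) + (1 - pa) * pb,
                    pa * pb,
                ],
                axis=-1,
            )
        else:
            triples = np.zeros((haps.shape[0] // 2, 0, 3))
        out[group] = triples
    return PosteriorGenotypes(
        site_ids=imputable, cases=out["cases"], controls=out["controls"],
        not_imputable=not_imputable,
    )


def call_genotypes(triples: np.ndarray, call_threshold: float = 0.9) -> np.ndarray:
    """Call argmax genotype where its posterior reaches the threshold.

    Entries whose maximum falls below the threshold, or where two genotypes
    tie at the maximum, are left missing.
    """
    p = np.asarray(triples, dtype=float)
    best = p.argmax(axis=-1)
    pmax = p.max(axis=-1)
    tied = (p == pmax[..., None]).sum(axis=-1) > 1
    calls = np.where((pmax >= call_threshold) & ~tied, best, MISSING)
    return calls.astype(np.int8)


def info_score(triples: np.ndarray) -> float:
    """Ratio-of-information certainty measure for one site.

    With e_i = p1 + 2*p2 and f_i = p1 + 4*p2 over the N individuals and
    theta = sum(e_i) / (2N):  info = 1 - sum(f_i - e_i^2) / (2N*theta*(1-theta)),
    defined as 1 at the theta boundaries {0, 1}.
    """
    p = np.asarray(triples, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of genotype probability triples")
    N = p.shape[0]
    if N < 1:
        raise ValueError("need at least one individual")
    e = p[:, 1] + 2.0 * p[:, 2]
    f = p[:, 1] + 4.0 * p[:, 2]
    theta = e.sum() / (2.0 * N)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    return float(1.0 - (f - e * e).sum() / (2.0 * N * theta * (1.0 - theta)))
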