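"""QC filters, allelic association statistics, and observed-vs-imputed
error accounting for masked sites."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MISSING, AlignmentError, CohortStudy, SiteInfo, risk_dosage


@dataclass(frozen=True)
class QCConfig:
    """Site filters: pooled MAF and Hardy-Weinberg in controls only."""

    min_maf: float = 0.01
    hwe_chi2_max: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.hwe_chi2_max <= 0:
            raise ValueError("hwe_chi2_max must be positive")


@dataclass
class AssociationResult:
    site_id: str
    counts: np.ndarray  # 2x2: rows case/control, cols risk/other allele
    chi2: float
    p_value: float
    odds_ratio: float  # NaN when a zero cell makes it inestimable
    maf_study: float


@dataclass
class ErrorTally:
    """Per-masked-site comparison of observed and imputed genotypes."""

    site_id: str
    n_concordant: int = 0
    n_discordant: int = 0
    n_missing: int = 0
    risk_copies_lost_discordant: int = 0
    risk_copies_gained_discordant: int = 0
    risk_copies_retained: int = 0
    risk_copies_in_missing: int = 0
    other_copies_in_missing: int = 0
    monomorphic: bool = False
    false_negative: bool = False
    observed_chi2: float = np.nan
    observed_p: float = np.nan
    imputed_chi2: float = np.nan
    imputed_p: float = np.nan


def _allele_freq(genos: np.ndarray) -> tuple[float, int]:
    """Alt-allele frequency over non-missing genotypes; returns (freq, 2n)."""
    ok = genos != MISSING
    n2 = 2 * int(ok.sum())
    if n2 == 0:
        return np.nan, 0
    return float(genos[ok].sum()) / n2, n2


def hwe_chi2(genotypes: np.ndarray) -> float:
    """1-df Pearson statistic against Hardy-Weinberg expectations.

    Expected genotype counts derive from the observed allele frequency in
    the same sample; all-missing or monomorphic input gives 0.
    """
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    n = g.size
    if n == 0:
        return 0.0
    obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], dtype=float)
    q = g.sum() / (2 * n)  # alt freq
    p = 1.0 - q
    exp = n * np.array([p * p, 2 * p * q, q * q])
    mask = exp > 0
    return float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())


def qc_filter(study: CohortStudy, qc: QCConfig = QCConfig()) -> tuple[CohortStudy, list[tuple[str, str]]]:
    """Drop sites failing pooled-MAF or control-HWE filters.

    Returns the filtered study and ``(site_id, reason)`` pairs, reason in
    {"no data", "maf", "hwe"}.
    """
    keep, excluded = [], []
    pooled = study.pooled()
    for j, site in enumerate(study.sites):
        freq, n2 = _allele_freq(pooled[:, j])
        if n2 == 0:
            excluded.append((site.id, "no data"))
            continue
        maf = min(freq, 1.0 - freq)
        if not maf > qc.min_maf:
            excluded.append((site.id, "maf"))
            continue
        if not hwe_chi2(study.controls[:, j]) < qc.hwe_chi2_max:
            excluded.append((site.id, "hwe"))
            continue
        keep.append(j)
    return study.subset_sites(keep), excluded


def _pearson_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        return 0.0, 1.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 0.0, 1.0
    exp = np.outer(rows, cols) / n
    chi2 = float(((t - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def allelic_chi2(
    case_genos: np.ndarray, control_genos: np.ndarray, site: SiteInfo
) -> AssociationResult:
    """Allelic (2x2 allele count) chi-square test, risk-allele oriented.

    Missing genotypes contribute nothing.  OR = (a*d)/(b*c) with a = risk
    alleles in cases, oriented so OR > 1 means risk-allele enrichment in
    cases; any zero cell yields OR = NaN.
    """
    rows = []
    for genos in (case_genos, control_genos):
        d = risk_dosage(np.asarray(genos), site) if site.is_associated else np.asarray(genos)
        ok = d != MISSING
        if not ok.any():
            raise ValueError(f"site {site.id}: a group has no non-missing genotypes")
        risk = int(d[ok].sum())
        rows.append([risk, 2 * int(ok.sum()) - risk])
    table = np.array(rows, dtype=np.int64)
    chi2, p = _pearson_2x2(table)
    a, b = table[0]
    c, d_ = table[1]
    odds = (a * d_) / (b * c) if min(a, b, c, d_) > 0 else np.nan
    alt_freq, _ = _allele_freq(np.concatenate([np.asarray(case_genos).ravel(),
                                               np.asarray(control_genos).ravel()]))
    maf = min(alt_freq, 1 - alt_freq) if np.isfinite(alt_freq) else np.nan
    return AssociationResult(
        site_id=site.id, counts=table, chi2=chi2, p_value=p, odds_ratio=float(odds), maf_study=maf
    )


def ld_r2(panel, site_a: int | str, site_b: int | str) -> float:
    """Squared correlation of two binary haplotype columns."""
    idx = panel.site_index()
    ia = idx[site_a] if isinstance(site_a, str) else int(site_a)
    ib = idx[site_b] if isinstance(site_b, str) else int(site_b)
    x = panel.alleles[:, ia].astype(float)
    y = panel.alleles[:, ib].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"LD undefined: monomorphic column ({site_a!r} or {site_b!r})")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _imputed_association(
    imp_cases: np.ndarray, imp_controls: np.ndarray, site: SiteInfo
) -> tuple[float, float]:
    """Association on imputed calls; NaN when a group has no calls or the
    called set is monomorphic (chi-square trivially 0 is reported as such)."""
    try:
        res = allelic_chi2(imp_cases, imp_controls, site)
    except ValueError:
        return np.nan, np.nan
    return res.chi2, res.p_value


def compare_observed_imputed(
    observed: CohortStudy,
    imputed_cases: np.ndarray,
    imputed_controls: np.ndarray,
    masked_site_ids: list[str],
    alpha: float = 0.05,
) -> list[ErrorTally]:
    """Classify every (individual, masked site) entry and tally allele-level
    errors in risk-allele units.

    Entries where imputation made no call count as missing; risk copies
    "lost"/"gained" are summed over discordant entries; ``monomorphic`` means
    the called genotypes (missing excluded) show one allele only;
    ``false_negative`` means the observed test is significant at ``alpha``
    while the imputed one is not (or cannot be computed).
    """
    sidx = observed.site_index()
    unknown = [s for s in masked_site_ids if s not in sidx]
    if unknown:
        raise AlignmentError(f"masked sites absent from observed study: {unknown}")
    imputed_cases = np.asarray(imputed_cases)
    imputed_controls = np.asarray(imputed_controls)
    if imputed_cases.shape != (observed.n_cases, len(masked_site_ids)) or \
       imputed_controls.shape != (observed.n_controls, len(masked_site_ids)):
        raise AlignmentError(
            "imputed matrices must be (n_individuals x n_masked_sites) aligned with the study"
        )
    tallies = []
    for k, sid in enumerate(masked_site_ids):
        j = sidx[sid]
        site = observed.sites[j]
        obs = np.concatenate([observed.cases[:, j], observed.controls[:, j]])
        imp = np.concatenate([imputed_cases[:, k], imputed_controls[:, k]])
        t = ErrorTally(site_id=sid)
        missing = (imp == MISSING) | (obs == MISSING)
        called = ~missing
        t.n_missing = int(missing.sum())
        t.n_concordant = int((obs[called] == imp[called]).sum())
        t.n_discordant = int((obs[called] != imp[called]).sum())

        if site.is_associated:
            obs_r = risk_dosage(obs, site)
            imp_r = risk_dosage(imp, site)
        else:  # orient on alt allele when no risk designation exists
            obs_r, imp_r = obs, imp
        disc = called & (obs != imp)
        diff = obs_r[disc].astype(int) - imp_r[disc].astype(int)
        t.risk_copies_lost_discordant = int(np.maximum(diff, 0).sum())
        t.risk_copies_gained_discordant = int(np.maximum(-diff, 0).sum())
        t.risk_copies_retained = int(
            np.minimum(obs_r[called].astype(int), imp_r[called].astype(int)).sum()
        )
        obs_miss = obs_r[missing & (obs != MISSING)].astype(int)
        t.risk_copies_in_missing = int(obs_miss.sum())
        t.other_copies_in_missing = int((2 - obs_miss).sum())

        calls = imp[imp != MISSING]
        alleles_seen = set()
        if np.isin(calls, (0, 1)).any():
            alleles_seen.add("ref")
        if np.isin(calls, (1, 2)).any():
            alleles_seen.add("alt")
        t.monomorphic = calls.size > 0 and len(alleles_seen) == 1

        obs_res = allelic_chi2(observed.cases[:, j], observed.controls[:, j], site)
        t.observed_chi2, t.observed_p = obs_res.chi2, obs_res.p_value
        t.imputed_chi2, t.imputed_p = _imputed_association(
            imputed_cases[:, k], imputed_controls[:, k], site
        )
        observed_sig = t.observed_p < alpha
        imputed_sig = np.isfinite(t.imputed_p) and t.imputed_p < alpha
        t.false_negative = bool(observed_sig and (not imputed_sig or t.monomorphic))
        tallies.append(t)
    return tallies
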