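"""Generator for reference haplotype panels and case-control cohorts.

The generative law is deliberately simple: a small set of founder haplotypes
is resampled with group-specific frequencies, with independent per-site flip
noise and at most one crossover per sampled haplotype.  Risk haplotypes ride
a shared background and are enriched in cases relative to the reference
panel, which is the statistical structure the masking experiments probe.

Founder layout produced by :func:`build_founders` (labels in parentheses):

* founder 0 (``background``): the common background haplotype;
* one or two risk lineages.  Each lineage has an *archetype* founder
  (``risk<k>``) present in the reference panel and a *variant* founder
  (``risk<k>_variant``) carrying the same risk alleles on the same
  background but with its own private scaffold markers.  Presets give the
  variant zero reference frequency, so case risk haplotypes are absent from
  the reference panel — the mechanism that defeats imputation;
* remaining founders (``other<k>``): independent random backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CohortStudy, HaplotypePanel, SiteInfo

ARCHITECTURES = ("monophyletic", "polyphyletic")


@dataclass
class SimulationConfig:
    """Full description of one simulated region."""

    founder_haplotypes: HaplotypePanel
    founder_freqs_reference: np.ndarray
    founder_freqs_cases: np.ndarray
    founder_freqs_controls: np.ndarray
    n_reference_haps: int = 1000
    n_cases: int = 92
    n_controls: int = 93
    mutation_rate: float = 0.0
    recombination_rate: float = 0.0
    seed: int = 0
    name: str = "region"

    def __post_init__(self) -> None:
        nf = self.founder_haplotypes.n_haplotypes
        for attr in ("founder_freqs_reference", "founder_freqs_cases", "founder_freqs_controls"):
            v = np.asarray(getattr(self, attr), dtype=float)
            setattr(self, attr, v)
            if v.shape != (nf,):
                raise ValueError(f"{attr}: expected {nf} entries, got shape {v.shape}")
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{attr}: must be non-negative and sum to 1 within 1e-12")
        for attr in ("mutation_rate", "recombination_rate"):
            r = getattr(self, attr)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {r}")
        if self.n_reference_haps < 1:
            raise ValueError("n_reference_haps must be positive")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")


def _make_sites(
    rng: np.random.Generator,
    n_sites: int,
    assoc_idx: np.ndarray,
    chrom: str,
    start_bp: int,
    region_kb: float,
) -> list[SiteInfo]:
    span = max(int(round(region_kb * 1000)), n_sites + 1)
    pos = start_bp + np.sort(rng.choice(span, size=n_sites, replace=False))
    assoc = set(int(i) for i in assoc_idx)
    sites = []
    for i in range(n_sites):
        is_assoc = i in assoc
        sites.append(
            SiteInfo(
                id=f"c{chrom}_s{i:04d}",
                chrom=chrom,
                pos_bp=int(pos[i]),
                ref_allele="A",
                alt_allele="G",
                risk_allele="alt" if is_assoc else "none",
                is_associated=is_assoc,
            )
        )
    return sites


def build_founders(
    n_founders: int,
    n_sites: int,
    n_associated: int,
    architecture: str = "monophyletic",
    seed: int = 0,
    *,
    n_private_markers: int = 2,
    region_kb: float = 40.0,
    chrom: str = "1",
    start_bp: int = 1_000_000,
) -> HaplotypePanel:
    """Construct founder haplotypes with designated risk lineages.

    Under ``monophyletic`` every risk founder carries the alt allele at all
    associated sites; under ``polyphyletic`` two lineages carry differing
    non-empty subsets.  Non-risk founders never carry a risk allele.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"architecture must be one of {ARCHITECTURES}")
    if n_associated > n_sites:
        raise ValueError(f"n_associated ({n_associated}) exceeds n_sites ({n_sites})")
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if architecture == "polyphyletic" and n_associated < 2:
        raise ValueError("polyphyletic architecture needs >= 2 associated sites")

    rng = np.random.default_rng(seed)
    assoc_idx = np.sort(rng.choice(n_sites, size=n_associated, replace=False))
    nonassoc_idx = np.setdiff1d(np.arange(n_sites), assoc_idx)
    sites = _make_sites(rng, n_sites, assoc_idx, chrom, start_bp, region_kb)

    alleles = np.zeros((n_founders, n_sites), dtype=np.int8)
    # independent random backgrounds at non-associated sites, all founders
    alleles[:, nonassoc_idx] = (rng.random((n_founders, nonassoc_idx.size)) < 0.5).astype(np.int8)

    n_lineages = 1 if architecture == "monophyletic" else 2
    # founders 1..2*n_lineages are risk founders: archetype + variant per
    # lineage, both riding founder 0's background
    n_risk = min(2 * n_lineages, n_founders - 1)
    labels = ["background"]
    if n_associated > 0 and n_risk >= 1:
        if n_lineages == 2:
            half = (n_associated + 1) // 2
            subsets = [assoc_idx, assoc_idx[:half]]
        else:
            subsets = [assoc_idx]
        priv_pool = nonassoc_idx.copy()
        rng.shuffle(priv_pool)
        taken = 0
        for f in range(1, n_risk + 1):
            lineage = (f - 1) // 2
            role = "variant" if (f - 1) % 2 else ""
            alleles[f] = alleles[0]
            alleles[f, subsets[min(lineage, len(subsets) - 1)]] = 1
            npriv = n_private_markers
            priv = priv_pool[taken:taken + min(npriv, max(priv_pool.size - taken, 0))]
            taken += priv.size
            alleles[f, priv] = 1 - alleles[f, priv]
            labels.append(f"risk{lineage}_variant" if role else f"risk{lineage}")
    labels += [f"other{k}" for k in range(n_founders - len(labels))]
    return HaplotypePanel(alleles=alleles, sites=sites, labels=labels)


def risk_founder_indices(founders: HaplotypePanel) -> np.ndarray:
    """Indices of founders that carry >= 1 risk allele at an associated site."""
    assoc = [i for i, s in enumerate(founders.sites) if s.is_associated]
    if not assoc:
        return np.array([], dtype=np.intp)
    return np.flatnonzero(founders.alleles[:, assoc].any(axis=1))


def _sample_noisy_haplotypes(
    config: SimulationConfig, freqs: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n haplotypes: founder copy + optional single crossover + flips."""
    founders = config.founder_haplotypes.alleles
    nf, L = founders.shape
    origin = rng.choice(nf, size=n, p=freqs)
    haps = founders[origin].copy()
    if config.recombination_rate > 0 and L > 1:
        rec = rng.random(n) < config.recombination_rate
        for i in np.flatnonzero(rec):
            donor = int(rng.integers(nf))
            cut = int(rng.integers(1, L))
            haps[i, cut:] = founders[donor, cut:]
    if config.mutation_rate > 0:
        flips = rng.random(haps.shape) < config.mutation_rate
        haps ^= flips.astype(np.int8)
    return haps, origin


def sample_reference_panel(config: SimulationConfig) -> HaplotypePanel:
    """Sample the phased reference panel; deterministic given ``config.seed``."""
    rng = np.random.default_rng([config.seed, 0])
    haps, origin = _sample_noisy_haplotypes(
        config, config.founder_freqs_reference, config.n_reference_haps, rng
    )
    flabels = config.founder_haplotypes.labels or [str(i) for i in range(len(origin))]
    return HaplotypePanel(
        alleles=haps,
        sites=list(config.founder_haplotypes.sites),
        labels=[flabels[i] for i in origin],
    )


def sample_cohort(config: SimulationConfig) -> CohortStudy:
    """Sample the case-control cohort under random (Hardy-Weinberg) mating.

    Each individual is two haplotypes drawn i.i.d. from the group-specific
    founder distribution; genotypes are their column-wise sums.  Truth
    haplotypes are retained.  Deterministic given ``config.seed``.
    """
    sites = list(config.founder_haplotypes.sites)
    flabels = config.founder_haplotypes.labels or []
    out: dict[str, HaplotypePanel] = {}
    for stream, (group, freqs, n) in enumerate(
        [
            ("cases", config.founder_freqs_cases, config.n_cases),
            ("controls", config.founder_freqs_controls, config.n_controls),
        ],
        start=1,
    ):
        rng = np.random.default_rng([config.seed, stream])
        haps, origin = _sample_noisy_haplotypes(config, freqs, 2 * n, rng)
        labels = [flabels[i] if flabels else str(i) for i in origin]
        out[group] = HaplotypePanel(alleles=haps, sites=sites, labels=labels)
    case_g = out["cases"].alleles[0::2] + out["cases"].alleles[1::2]
    ctrl_g = out["controls"].alleles[0::2] + out["controls"].alleles[1::2]
    return CohortStudy(
        cases=case_g,
        controls=ctrl_g,
        sites=sites,
        truth_case_haps=out["cases"],
        truth_control_haps=out["controls"],
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPreset:
    name: str
    chrom: str
    n_sites: int
    length_kb: float
    n_associated: int
    architecture: str


#: geometry of the three emulated regions: site counts, lengths and number
#: of associated sites per region, plus one polyphyletic architecture
REGION_PRESETS: tuple[RegionPreset, ...] = (
    RegionPreset("regionA", "1", 118, 39.4, 7, "polyphyletic"),
    RegionPreset("regionB", "2", 59, 40.9, 8, "monophyletic"),
    RegionPreset("regionC", "3", 20, 8.3, 8, "monophyletic"),
)

#: enrichment defaults: total risk-haplotype frequency by group
RISK_FREQ_CASES = 0.25
RISK_FREQ_REFERENCE = 0.10


def _preset_freqs(
    labels: list[str], risk_cases: float, risk_reference: float, enriched: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split group risk mass over lineages; variants dominate in cases only."""
    n = len(labels)
    is_variant = np.array([lb.endswith("_variant") for lb in labels])
    is_arch = np.array([lb.startswith("risk") and not lb.endswith("_variant") for lb in labels])
    is_bg = np.array([lb == "background" for lb in labels])
    is_other = ~(is_variant | is_arch | is_bg)
    n_var, n_arch = int(is_variant.sum()), int(is_arch.sum())

    def make(total_risk: float, var_share: float, bg: float) -> np.ndarray:
        f = np.zeros(n)
        if n_var + n_arch:
            f[is_variant] = total_risk * var_share / max(n_var, 1)
            f[is_arch] = total_risk * (1 - var_share) / max(n_arch, 1)
        f[is_bg] = bg
        rest = 1.0 - f.sum()
        f[is_other] = rest / max(int(is_other.sum()), 1)
        return f

    # enriched: case risk mass sits on study-private variant lineages that the
    # reference panel lacks entirely; null: all three columns share one law
    reference = make(risk_reference, 0.0 if enriched else 0.8, 0.30)
    controls = make(risk_reference, 0.8, 0.30)
    cases = make(risk_cases if enriched else risk_reference, 0.92 if enriched else 0.8, 0.25 if enriched else 0.30)
    return reference, cases, controls


def preset_configs(
    seed: int = 0,
    enriched: bool = True,
    *,
    n_cases: int = 92,
    n_controls: int = 93,
    n_reference_haps: int = 1000,
    risk_freq_cases: float = RISK_FREQ_CASES,
    risk_freq_reference: float = RISK_FREQ_REFERENCE,
    mutation_rate: float = 0.002,
    recombination_rate: float = 0.01,
) -> list[SimulationConfig]:
    """Build the three-region emulation preset (``enriched=False`` -> null)."""
    configs = []
    for k, rp in enumerate(REGION_PRESETS):
        founders = build_founders(
            8 if rp.architecture == "polyphyletic" else 7,
            rp.n_sites,
            rp.n_associated,
            rp.architecture,
            seed=seed * 1009 + k,
            region_kb=rp.length_kb,
            chrom=rp.chrom,
        )
        ref_f, case_f, ctrl_f = _preset_freqs(
            founders.labels or [], risk_freq_cases, risk_freq_reference, enriched
        )
        configs.append(
            SimulationConfig(
                founder_haplotypes=founders,
                founder_freqs_reference=ref_f,
                founder_freqs_cases=case_f,
                founder_freqs_controls=ctrl_f,
                n_reference_haps=n_reference_haps,
                n_cases=n_cases,
                n_controls=n_controls,
                mutation_rate=mutation_rate,
                recombination_rate=recombination_rate,
                seed=seed * 7919 + k,
                name=rp.name,
            )
        )
    return configs
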