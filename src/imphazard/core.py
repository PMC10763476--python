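"""Shared domain types: sites, haplotype panels, and case-control cohorts.

Genotypes are stored as ``int8`` alt-allele counts (0/1/2) with ``MISSING``
(-1) for uncalled entries.  Haplotype panels are dense 0/1 matrices of shape
(haplotypes, sites).  All site lists are ordered by physical position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel for an uncalled genotype
MISSING: int = -1

_RISK_VALUES = ("ref", "alt", "none")


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class AlignmentError(PipelineError):
    """Two containers that must cover identical sites/individuals do not."""


@dataclass(frozen=True)
class SiteInfo:
    """Metadata for one biallelic SNP."""

    id: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    risk_allele: str = "none"
    is_associated: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele not in _RISK_VALUES:
            raise ValueError(f"risk_allele must be one of {_RISK_VALUES}, got {self.risk_allele!r}")
        if self.is_associated != (self.risk_allele != "none"):
            raise ValueError(
                f"site {self.id}: risk_allele must be set iff is_associated "
                f"(got risk_allele={self.risk_allele!r}, is_associated={self.is_associated})"
            )
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"site {self.id}: alleles must be single characters")
        if self.pos_bp < 1:
            raise ValueError(f"site {self.id}: pos_bp must be 1-based positive")

    @property
    def risk_is_alt(self) -> bool:
        return self.risk_allele == "alt"


def validate_sites(sites: list[SiteInfo]) -> None:
    """Check strictly increasing positions within each chromosome run."""
    for a, b in zip(sites, sites[1:]):
        if a.chrom == b.chrom and b.pos_bp <= a.pos_bp:
            raise ValueError(f"site positions not strictly increasing: {a.id} -> {b.id}")


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over an ordered list of sites.

    ``alleles`` has shape (H, L) with entries in {0, 1}; ``labels`` is an
    optional per-haplotype group tag (e.g. originating founder).
    """

    alleles: np.ndarray
    sites: list[SiteInfo]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError(
                f"column count {self.alleles.shape[1]} != number of sites {len(self.sites)}"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype panel entries must all be 0/1 (no missing allowed)")
        if self.labels is not None and len(self.labels) != self.alleles.shape[0]:
            raise ValueError("labels length must equal haplotype count")
        validate_sites(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.sites], dtype=np.int64)

    def alt_freqs(self) -> np.ndarray:
        """Alt-allele frequency per site."""
        return self.alleles.mean(axis=0)

    def subset_sites(self, indices: np.ndarray | list[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(
            alleles=self.alleles[:, idx],
            sites=[self.sites[i] for i in idx],
            labels=self.labels,
        )

    def subset_haplotypes(self, indices: np.ndarray | list[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        labels = [self.labels[i] for i in idx] if self.labels is not None else None
        return HaplotypePanel(alleles=self.alleles[idx], sites=list(self.sites), labels=labels)

    def site_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.sites)}


@dataclass
class CohortStudy:
    """Case and control genotype matrices over a shared ordered site list.

    ``truth_case_haps`` / ``truth_control_haps``, when present (simulation
    only), hold 2N phased haplotypes with rows (2i, 2i+1) belonging to
    individual i.
    """

    cases: np.ndarray
    controls: np.ndarray
    sites: list[SiteInfo]
    truth_case_haps: HaplotypePanel | None = None
    truth_control_haps: HaplotypePanel | None = None
    case_ids: list[str] = field(default_factory=list)
    control_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cases = np.asarray(self.cases, dtype=np.int8)
        self.controls = np.asarray(self.controls, dtype=np.int8)
        for name, g in (("cases", self.cases), ("controls", self.controls)):
            if g.ndim != 2 or g.shape[1] != len(self.sites):
                raise ValueError(f"{name} matrix shape {g.shape} inconsistent with site list")
            if g.size and not np.isin(g, (0, 1, 2, MISSING)).all():
                raise ValueError(f"{name} genotypes must be 0/1/2 or missing ({MISSING})")
        validate_sites(self.sites)
        if not self.case_ids:
            self.case_ids = [f"case{i:03d}" for i in range(self.cases.shape[0])]
        if not self.control_ids:
            self.control_ids = [f"ctrl{i:03d}" for i in range(self.controls.shape[0])]
        for hp, n in ((self.truth_case_haps, self.cases.shape[0]),
                      (self.truth_control_haps, self.controls.shape[0])):
            if hp is not None and hp.n_haplotypes != 2 * n:
                raise ValueError("truth haplotype panel must have 2 rows per individual")

    @property
    def n_cases(self) -> int:
        return self.cases.shape[0]

    @property
    def n_controls(self) -> int:
        return self.controls.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def pooled(self) -> np.ndarray:
        """Stacked case + control genotype matrix."""
        return np.vstack([self.cases, self.controls])

    def site_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.sites)}

    def associated_ids(self) -> list[str]:
        return [s.id for s in self.sites if s.is_associated]

    def subset_sites(self, indices: np.ndarray | list[int]) -> "CohortStudy":
        idx = np.asarray(indices, dtype=np.intp)
        return CohortStudy(
            cases=self.cases[:, idx],
            controls=self.controls[:, idx],
            sites=[self.sites[i] for i in idx],
            truth_case_haps=(self.truth_case_haps.subset_sites(idx)
                             if self.truth_case_haps is not None else None),
            truth_control_haps=(self.truth_control_haps.subset_sites(idx)
                                if self.truth_control_haps is not None else None),
            case_ids=list(self.case_ids),
            control_ids=list(self.control_ids),
        )


def risk_dosage(genotypes: np.ndarray, site: SiteInfo) -> np.ndarray:
    """Convert alt-allele counts to risk-allele counts; missing stays missing."""
    g = np.asarray(genotypes)
    if site.risk_allele == "none":
        raise ValueError(f"site {site.id} has no designated risk allele")
    if site.risk_is_alt:
        return g.copy()
    out = np.where(g == MISSING, MISSING, 2 - g)
    return out.astype(g.dtype)
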