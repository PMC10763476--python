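"""Haplotype frequency tables across cases, controls, pooled study and the
reference panel, with risk-lineage architecture classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypePanel, SiteInfo


@dataclass
class HaplotypeFreqRow:
    haplotype: str  # binary string over the chosen site subset
    carries_risk: bool
    freq_cases: float
    freq_controls: float
    freq_pooled: float
    freq_reference: float
    enrichment: float  # freq_cases / freq_reference; NaN if reference freq 0


def _freqs(alleles: np.ndarray) -> dict[str, float]:
    total = alleles.shape[0]
    out: dict[str, float] = {}
    for row in alleles:
        key = "".join(map(str, row.tolist()))
        out[key] = out.get(key, 0.0) + 1.0
    return {k: v / total for k, v in out.items()}


def haplotype_table(
    case_haps: HaplotypePanel,
    control_haps: HaplotypePanel,
    reference: HaplotypePanel,
    site_subset: list[str] | None = None,
) -> list[HaplotypeFreqRow]:
    """Group haplotypes by exact identity on ``site_subset`` and tabulate
    per-column frequencies, sorted by case frequency (descending).

    All three panels must cover the subset; ``carries_risk`` is true iff the
    haplotype bears >= 1 risk allele at an associated subset site.
    """
    if site_subset is None:
        site_subset = case_haps.site_ids
    if not site_subset:
        raise ValueError("site_subset must be non-empty")
    panels = {}
    for name, panel in (("cases", case_haps), ("controls", control_haps),
                        ("reference", reference)):
        idx_map = panel.site_index()
        missing = [s for s in site_subset if s not in idx_map]
        if missing:
            raise ValueError(f"{name} panel lacks subset sites {missing}")
        panels[name] = panel.subset_sites([idx_map[s] for s in site_subset])

    sub_sites = panels["cases"].sites
    risk_mask = np.array(
        [1 if s.is_associated and s.risk_is_alt else 0 for s in sub_sites], dtype=np.int8
    )
    risk_ref_mask = np.array(
        [1 if s.is_associated and s.risk_allele == "ref" else 0 for s in sub_sites], dtype=np.int8
    )

    f_cases = _freqs(panels["cases"].alleles)
    f_ctrl = _freqs(panels["controls"].alleles)
    f_ref = _freqs(panels["reference"].alleles)
    n_ca = panels["cases"].alleles.shape[0]
    n_co = panels["controls"].alleles.shape[0]

    rows = []
    for key in sorted(set(f_cases) | set(f_ctrl) | set(f_ref)):
        bits = np.frombuffer(key.encode(), dtype=np.uint8) - ord("0")
        carries = bool((bits & risk_mask).any() or ((1 - bits) & risk_ref_mask).any())
        fc = f_cases.get(key, 0.0)
        fo = f_ctrl.get(key, 0.0)
        fr = f_ref.get(key, 0.0)
        pooled = (fc * n_ca + fo * n_co) / (n_ca + n_co)
        rows.append(
            HaplotypeFreqRow(
                haplotype=key,
                carries_risk=carries,
                freq_cases=fc,
                freq_controls=fo,
                freq_pooled=pooled,
                freq_reference=fr,
                enrichment=fc / fr if fr > 0 else float("nan"),
            )
        )
    rows.sort(key=lambda r: (-r.freq_cases, r.haplotype))
    return rows


def classify_architecture(
    rows: list[HaplotypeFreqRow], sites: list[SiteInfo], site_subset: list[str] | None = None
) -> str:
    """``monophyletic`` iff every risk-carrying haplotype bears the identical
    risk-allele subset at the associated sites; else ``polyphyletic``."""
    if site_subset is None:
        site_subset = [s.id for s in sites]
    by_id = {s.id: s for s in sites}
    sub_sites = [by_id[sid] for sid in site_subset]
    assoc_pos = [
        (i, 1 if s.risk_is_alt else 0) for i, s in enumerate(sub_sites) if s.is_associated
    ]
    risk_rows = [r for r in rows if r.carries_risk]
    if not risk_rows:
        raise ValueError("no risk haplotypes observed")
    subsets = set()
    for r in risk_rows:
        carried = frozenset(
            i for i, risk_bit in assoc_pos if int(r.haplotype[i]) == risk_bit
        )
        subsets.add(carried)
    return "monophyletic" if len(subsets) == 1 else "polyphyletic"


def table_to_frame(rows: list[HaplotypeFreqRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "haplotype": [r.haplotype for r in rows],
            "carries_risk": [r.carries_risk for r in rows],
            "freq_cases": [r.freq_cases for r in rows],
            "freq_controls": [r.freq_controls for r in rows],
            "freq_pooled": [r.freq_pooled for r in rows],
            "freq_reference": [r.freq_reference for r in rows],
            "enrichment": [r.enrichment for r in rows],
        }
    )
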