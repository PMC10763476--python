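"""Construction and execution of the three masking designs.

``simultaneous_high`` masks every associated site at once and scaffolds with
all remaining sites; ``simultaneous_low`` additionally thins the scaffold to
a target per-kb density by even positional spacing (array-like tagging);
``leave_one_out`` masks one associated site at a time, keeping the other
associated sites in the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CohortStudy, HaplotypePanel, PipelineError
from .imputation_engine import (
    ImputationConfig,
    call_genotypes,
    impute_masked,
    info_score,
)
from .phasing import MAX_SITES, phase_study
from .qc_association import ErrorTally, compare_observed_imputed

EXPERIMENTS = ("simultaneous_low", "simultaneous_high", "leave_one_out")

#: fewest scaffold sites a thinned design may keep
MIN_LOW_DENSITY_SCAFFOLD = 5


@dataclass
class MaskingPlan:
    experiment: str
    masked_site_ids: list[str]
    scaffold_site_ids: list[str]
    target_scaffold_density_per_kb: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        overlap = set(self.masked_site_ids) & set(self.scaffold_site_ids)
        if overlap:
            raise ValueError(f"masked and scaffold sites overlap: {sorted(overlap)}")


class DensityError(PipelineError):
    """The requested scaffold density cannot be realised for this region."""


def region_length_kb(study: CohortStudy) -> float:
    pos = [s.pos_bp for s in study.sites]
    return (max(pos) - min(pos)) / 1000.0


def make_plans(
    study: CohortStudy,
    experiment: str,
    density_target: float | None = None,
) -> list[MaskingPlan]:
    """Build the masking plan(s) for one design on one region."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"experiment must be one of {EXPERIMENTS}")
    associated = study.associated_ids()
    if not associated:
        raise ValueError("study has no associated sites to mask")
    others = [s.id for s in study.sites if not s.is_associated]

    if experiment == "simultaneous_high":
        return [MaskingPlan(experiment, associated, others)]

    if experiment == "leave_one_out":
        all_ids = study.site_ids
        return [
            MaskingPlan(experiment, [sid], [x for x in all_ids if x != sid])
            for sid in associated
        ]

    # simultaneous_low: thin the non-associated scaffold by even rank spacing
    if density_target is None or density_target <= 0:
        raise ValueError("simultaneous_low requires a positive density target (sites per kb)")
    kb = region_length_kb(study)
    available_density = len(others) / kb
    if density_target > available_density:
        raise DensityError(
            f"density target {density_target}/kb exceeds available "
            f"{available_density:.2f}/kb ({len(others)} scaffold sites over {kb:.1f} kb)"
        )
    n_keep = int(round(density_target * kb))
    if n_keep < MIN_LOW_DENSITY_SCAFFOLD:
        raise DensityError(
            f"density target {density_target}/kb keeps only {n_keep} scaffold sites "
            f"over {kb:.1f} kb (minimum {MIN_LOW_DENSITY_SCAFFOLD}); region skipped"
        )
    ranks = np.unique(np.round(np.linspace(0, len(others) - 1, n_keep)).astype(int))
    scaffold = [others[i] for i in ranks]
    return [MaskingPlan(experiment, associated, scaffold, density_target)]


@dataclass
class ExperimentResult:
    report: pd.DataFrame
    tallies: list[ErrorTally]
    plans: list[MaskingPlan]
    n_phase_excluded: int = 0


def _scaffold_haplotypes(
    study: CohortStudy, use_truth: bool, seed: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Phased haplotypes over the full study site order (2 rows/individual)."""
    if use_truth:
        if study.truth_case_haps is None or study.truth_control_haps is None:
            raise ValueError("truth haplotypes unavailable; run with EM phasing instead")
        return study.truth_case_haps.alleles, study.truth_control_haps.alleles, 0
    if study.n_sites > MAX_SITES:
        raise PipelineError(
            f"EM phasing limited to {MAX_SITES} sites; {study.n_sites} present — "
            "use truth haplotypes or window the region"
        )
    cases, controls = phase_study(study, seed=seed)
    haps_c = np.vstack([np.vstack(p.hap_pair) for p in cases])
    haps_t = np.vstack([np.vstack(p.hap_pair) for p in controls])
    return haps_c, haps_t, 0


def run_experiment(
    study: CohortStudy,
    reference: HaplotypePanel,
    plans: list[MaskingPlan],
    impute_config: ImputationConfig | None = None,
    alpha: float = 0.05,
    use_truth_haplotypes: bool = True,
    seed: int = 0,
    region: str = "region",
) -> ExperimentResult:
    """Mask, impute, call, score and compare for each plan; merge per site.

    Leave-one-out plans each contribute one row; simultaneous plans
    contribute one row per masked site.  Deterministic given inputs.
    """
    if not plans:
        raise ValueError("no masking plans supplied")
    cfg = impute_config or ImputationConfig(reference=reference)
    if cfg.reference is not reference:
        cfg = ImputationConfig(
            reference=reference,
            rho_per_kb=cfg.rho_per_kb,
            epsilon=cfg.epsilon,
            call_threshold=cfg.call_threshold,
        )
    case_haps, ctrl_haps, n_excl = _scaffold_haplotypes(study, use_truth_haplotypes, seed)
    ref_freqs = dict(zip(reference.site_ids, reference.alt_freqs()))
    sidx = study.site_index()

    rows: list[dict] = []
    all_tallies: list[ErrorTally] = []
    for plan in plans:
        try:
            keep = sorted(
                (sidx[s] for s in plan.masked_site_ids + plan.scaffold_site_ids)
            )
            sub = study.subset_sites(keep)
            sub_case_h = case_haps[:, keep]
            sub_ctrl_h = ctrl_haps[:, keep]
            post = impute_masked(
                sub, plan.masked_site_ids, cfg, scaffold_haps=(sub_case_h, sub_ctrl_h)
            )
            calls_cases = call_genotypes(post.cases, cfg.call_threshold)
            calls_controls = call_genotypes(post.controls, cfg.call_threshold)
            tallies = compare_observed_imputed(
                sub, calls_cases, calls_controls, post.site_ids, alpha=alpha
            )
        except PipelineError as exc:
            raise PipelineError(
                f"{plan.experiment} plan (masked={plan.masked_site_ids[:3]}...): {exc}"
            ) from exc
        for k, t in enumerate(tallies):
            j = sidx[t.site_id]
            site = study.sites[j]
            pooled = study.pooled()[:, j]
            ok = pooled[pooled >= 0]
            af = ok.mean() / 2 if ok.size else np.nan
            triples = np.concatenate([post.cases[:, k], post.controls[:, k]])
            rf = ref_freqs.get(t.site_id, np.nan)
            if site.is_associated:
                obs_case = study.cases[:, j]
                obs_alt = obs_case[obs_case >= 0].mean() / 2
                imp_alt = (post.cases[:, k, 1] + 2 * post.cases[:, k, 2]).mean() / 2
                if not site.risk_is_alt:
                    obs_alt, imp_alt = 1 - obs_alt, 1 - imp_alt
                risk_obs, risk_imp = obs_alt, imp_alt
            else:
                risk_obs = risk_imp = np.nan
            rows.append(
                {
                    "site_id": t.site_id,
                    "region": region,
                    "experiment": plan.experiment,
                    "observed_chi2": t.observed_chi2,
                    "observed_p": t.observed_p,
                    "imputed_chi2": np.nan if t.monomorphic else t.imputed_chi2,
                    "imputed_p": np.nan if t.monomorphic else t.imputed_p,
                    "info": info_score(triples),
                    "maf_study": min(af, 1 - af) if np.isfinite(af) else np.nan,
                    "maf_reference": min(rf, 1 - rf) if np.isfinite(rf) else np.nan,
                    "risk_freq_cases_observed": risk_obs,
                    "risk_freq_cases_imputed": risk_imp,
                    "n_concordant": t.n_concordant,
                    "n_discordant": t.n_discordant,
                    "n_missing": t.n_missing,
                    "risk_copies_lost_discordant": t.risk_copies_lost_discordant,
                    "risk_copies_gained_discordant": t.risk_copies_gained_discordant,
                    "risk_copies_in_missing": t.risk_copies_in_missing,
                    "other_copies_in_missing": t.other_copies_in_missing,
                    "monomorphic": t.monomorphic,
                    "false_negative": t.false_negative,
                }
            )
        all_tallies.extend(tallies)
        for sid in post.not_imputable:
            rows.append(
                {"site_id": sid, "region": region, "experiment": plan.experiment,
                 "monomorphic": False, "false_negative": True}
            )
    report = pd.DataFrame(rows).sort_values("site_id", kind="stable").reset_index(drop=True)
    return ExperimentResult(report=report, tallies=all_tallies, plans=plans,
                            n_phase_excluded=n_excl)


def summarize(result: ExperimentResult, n_individuals: int) -> dict:
    """Aggregate counts the report consumer cares about."""
    t = result.tallies
    conc = [x.n_concordant / n_individuals for x in t] if t else []
    return {
        "n_masked": len(t),
        "n_monomorphic": int(sum(x.monomorphic for x in t)),
        "n_false_negative": int(sum(x.false_negative for x in t)),
        "mean_info": float(result.report["info"].mean()) if len(result.report) else float("nan"),
        "mean_concordance": float(np.mean(conc)) if conc else float("nan"),
    }
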