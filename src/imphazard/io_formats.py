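"""Readers and writers for the formats the pipeline touches.

VCF 4.2 for cohort genotypes (case/control membership in a two-column
sidecar file), plain-text hap/legend pairs for phased reference panels, and
TSV for report tables.  All writers are deterministic; reader/writer pairs
round-trip on valid inputs.  Alleles are never strand-flipped: study and
reference alleles must match byte-for-byte.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, CohortStudy, HaplotypePanel, PipelineError, SiteInfo


class ParseError(PipelineError):
    """Malformed or unsupported input file content."""


# ---------------------------------------------------------------------------
# VCF + sample-group sidecar
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=imphazard
##INFO=<ID=RISK,Number=1,Type=String,Description="Designated risk allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(study: CohortStudy, vcf_path: str | Path, groups_path: str | Path) -> None:
    """Write the cohort as an unphased VCF plus a sample-group sidecar TSV."""
    samples = list(study.case_ids) + list(study.control_ids)
    genos = study.pooled()
    lines = [_VCF_HEADER]
    for chrom in dict.fromkeys(s.chrom for s in study.sites):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, site in enumerate(study.sites):
        info = f"RISK={site.risk_allele}" if site.is_associated else "."
        gts = "\t".join(gt_map[int(g)] for g in genos[:, j])
        lines.append(
            f"{site.chrom}\t{site.pos_bp}\t{site.id}\t{site.ref_allele}\t{site.alt_allele}"
            f"\t.\tPASS\t{info}\tGT\t{gts}\n"
        )
    Path(vcf_path).write_text("".join(lines))
    with open(groups_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in study.case_ids:
            fh.write(f"{s}\tcase\n")
        for s in study.control_ids:
            fh.write(f"{s}\tcontrol\n")


def _read_groups(groups_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ParseError(f"{groups_path}: expected columns 'sample' and 'group'")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ParseError(f"{groups_path}: unknown group labels {sorted(bad)}")
    return dict(zip(df["sample"], df["group"]))


def read_vcf(vcf_path: str | Path, groups_path: str | Path) -> CohortStudy:
    """Read a biallelic-SNP VCF into a :class:`CohortStudy`.

    ``./.`` maps to missing; sites are sorted by (chrom, position);
    multiallelic or non-SNP records are rejected by id.
    """
    groups = _read_groups(groups_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise ParseError(f"samples missing from group sidecar: {unknown}")
    records = []
    for rec in vcf:
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ParseError(f"record {rid}: multiallelic records are not supported")
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ParseError(f"record {rid}: only biallelic SNPs are supported (got {rec.REF},{rec.ALT[0]})")
        risk = rec.INFO.get("RISK")
        site = SiteInfo(
            id=rid,
            chrom=rec.CHROM,
            pos_bp=rec.POS,
            ref_allele=rec.REF,
            alt_allele=rec.ALT[0],
            risk_allele=risk if risk is not None else "none",
            is_associated=risk is not None,
        )
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt = np.where(gt == 3, MISSING, gt)
        records.append((site, gt))
    vcf.close()
    if not records:
        raise ParseError(f"{vcf_path}: no records")
    records.sort(key=lambda r: (r[0].chrom, r[0].pos_bp))
    sites = [r[0] for r in records]
    geno = np.column_stack([r[1] for r in records]).astype(np.int8)
    case_idx = [i for i, s in enumerate(samples) if groups[s] == "case"]
    ctrl_idx = [i for i, s in enumerate(samples) if groups[s] == "control"]
    return CohortStudy(
        cases=geno[case_idx],
        controls=geno[ctrl_idx],
        sites=sites,
        case_ids=[samples[i] for i in case_idx],
        control_ids=[samples[i] for i in ctrl_idx],
    )


# ---------------------------------------------------------------------------
# hap / legend reference panels
# ---------------------------------------------------------------------------

def write_reference_panel(panel: HaplotypePanel, hap_path: str | Path, legend_path: str | Path) -> None:
    """One legend row per site (id pos allele0 allele1 [risk]); hap file is
    space-separated 0/1 with one row per site, one column per haplotype."""
    with open(legend_path, "w") as fh:
        fh.write("id position a0 a1 risk\n")
        for s in panel.sites:
            fh.write(f"{s.id} {s.pos_bp} {s.ref_allele} {s.alt_allele} {s.risk_allele}\n")
    np.savetxt(hap_path, panel.alleles.T, fmt="%d", delimiter=" ")


def read_reference_panel(hap_path: str | Path, legend_path: str | Path, chrom: str = "1") -> HaplotypePanel:
    legend = pd.read_csv(legend_path, sep=r"\s+", dtype={"id": str, "a0": str, "a1": str})
    need = {"id", "position", "a0", "a1"}
    if not need <= set(legend.columns):
        raise ParseError(f"{legend_path}: expected columns {sorted(need)}")
    raw = Path(hap_path).read_text().split("\n")
    rows = [r.split() for r in raw if r.strip()]
    if len(rows) != len(legend):
        raise ParseError(
            f"hap/legend row mismatch: {len(rows)} hap rows vs {len(legend)} legend rows"
        )
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{hap_path}: ragged rows (widths {sorted(widths)})")
    tokens = set().union(*map(set, rows))
    if not tokens <= {"0", "1"}:
        raise ParseError(f"{hap_path}: non-binary tokens {sorted(tokens - {'0', '1'})}")
    alleles = np.array(rows, dtype=np.int8).T  # (H, L)
    sites = []
    for _, row in legend.iterrows():
        risk = str(row["risk"]) if "risk" in legend.columns else "none"
        sites.append(
            SiteInfo(
                id=str(row["id"]),
                chrom=chrom,
                pos_bp=int(row["position"]),
                ref_allele=str(row["a0"]),
                alt_allele=str(row["a1"]),
                risk_allele=risk,
                is_associated=risk != "none",
            )
        )
    return HaplotypePanel(alleles=alleles, sites=sites)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

#: stable column order for per-site report tables
REPORT_COLUMNS = [
    "site_id",
    "region",
    "experiment",
    "observed_chi2",
    "observed_p",
    "imputed_chi2",
    "imputed_p",
    "info",
    "maf_study",
    "maf_reference",
    "risk_freq_cases_observed",
    "risk_freq_cases_imputed",
    "n_concordant",
    "n_discordant",
    "n_missing",
    "risk_copies_lost_discordant",
    "risk_copies_gained_discordant",
    "risk_copies_in_missing",
    "other_copies_in_missing",
    "monomorphic",
    "false_negative",
]


def write_report(table: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a per-site report TSV; monomorphic sites render imputed chi2 as '-'."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty report table")
    out = table.copy()
    for col in REPORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[REPORT_COLUMNS]
    mono = out["monomorphic"].fillna(False).astype(bool)
    for col in ("imputed_chi2", "imputed_p"):
        out[col] = out[col].map(lambda v: "-" if pd.isna(v) else f"{v:.6f}")
        out.loc[mono, col] = "-"
    for col in ("observed_chi2", "observed_p", "info", "maf_study", "maf_reference",
                "risk_freq_cases_observed", "risk_freq_cases_imputed"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.strip().splitlines():
            buf.write(f"# {line}\n")
    out.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str})
    for col in ("imputed_chi2", "imputed_p"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("-", np.nan), errors="coerce")
    return df
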