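"""Polygenic risk score computation, QC and risk-group assignment.

The score for individual *i* over panel variants *j* with effect weights
``w_j`` and mean weight ``w̄`` is::

    PRS_i = sum_j dosage_ij * w_j / w̄

i.e. the number of carried risk alleles expressed in units of an
average-effect allele. Missing dosages are either imputed at their
population expectation ``2 * f_j`` or counted as zero, per policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .panel import VariantPanel

__all__ = [
    "DosageMatrix",
    "PRSRecord",
    "QuintileThresholds",
    "QCReport",
    "AMD_RISK_THRESHOLDS",
    "extract_dosages",
    "qc_strong_effect",
    "compute_prs",
    "derive_quintile_thresholds",
    "assign_risk_group",
    "assign_risk_groups",
    "prs_frame",
    "write_prs_table",
    "read_prs_table",
]

log = logging.getLogger(__name__)

MissingPolicy = Literal["auto", "zero", "impute_freq"]


@dataclass(frozen=True)
class DosageMatrix:
    """Individuals x variants matrix of risk-allele counts with a missingness mask.

    ``dosage[i, j]`` is the number of risk alleles (0, 1 or 2) carried by
    individual ``i`` at panel variant ``j`` wherever ``missing_mask[i, j]``
    is False; masked cells are undefined.
    """

    individual_ids: tuple[str, ...]
    variant_rsids: tuple[str, ...]
    dosage: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.individual_ids), len(self.variant_rsids)
        if self.dosage.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosage.shape} != ({n}, {m})")
        if self.missing_mask.shape != (n, m):
            raise ValueError(f"missing_mask shape {self.missing_mask.shape} != ({n}, {m})")
        present = self.dosage[~self.missing_mask]
        if present.size and (present.min() < 0 or present.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_rsids)

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of individuals with a missing call."""
        return self.missing_mask.mean(axis=0)


@dataclass(frozen=True)
class PRSRecord:
    individual_id: str
    prs: float
    n_missing: int
    risk_group: int | None = None


@dataclass(frozen=True)
class QuintileThresholds:
    """Four ascending cut points partitioning scores into groups 1-5.

    Group 1 is ``prs <= c1``, group k (2-4) is ``c_{k-1} < prs <= c_k``
    and group 5 is ``prs > c4`` (boundaries closed on the left group).
    """

    cuts: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        c = self.cuts
        if len(c) != 4 or not all(c[i] < c[i + 1] for i in range(3)):
            raise ValueError(f"cuts must be four strictly ascending reals, got {c}")


#: Published demonstration thresholds for the 47-variant AMD panel.
AMD_RISK_THRESHOLDS = QuintileThresholds(cuts=(25.3, 29.9, 34.5, 39.1))


@dataclass(frozen=True)
class QCReport:
    """Outcome of the strong-effect missingness check.

    A panel variant with a large oriented odds ratio that is frequently
    missing undermines the score's predictive value, so such variants
    fail QC rather than merely warn.
    """

    missing_fraction: dict[str, float]
    strong_effect_flags: tuple[str, ...]
    or_threshold: float
    max_missing: float

    @property
    def passed(self) -> bool:
        return not self.strong_effect_flags


def extract_dosages(vcf_path, panel: VariantPanel) -> DosageMatrix:
    """Read risk-allele dosages for the panel variants from a VCF.

    Variants are matched by (chrom, pos); at a matched site the VCF
    REF/ALT pair must equal the panel's allele pair (in either order),
    otherwise a build/strand mismatch error is raised. Panel variants
    absent from the VCF, and uncalled genotypes, become missing cells.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = tuple(vcf.samples)
    n, m = len(samples), len(panel)
    dosage = np.zeros((n, m), dtype=np.int8)
    missing = np.ones((n, m), dtype=bool)

    by_site = {(v.chrom, v.pos): j for j, v in enumerate(panel.variants)}
    for rec in vcf:
        key = (str(rec.CHROM), int(rec.POS))
        j = by_site.get(key)
        if j is None:
            continue
        pv = panel.variants[j]
        alts = rec.ALT or []
        if len(alts) != 1 or {rec.REF, alts[0]} != {pv.ref_allele, pv.alt_allele}:
            raise ValueError(
                f"allele mismatch at {pv.rsid} ({pv.chrom}:{pv.pos}): VCF has "
                f"{rec.REF}/{','.join(alts) or '.'}, panel has "
                f"{pv.ref_allele}/{pv.alt_allele}"
            )
        risk_idx = 0 if pv.risk_allele == rec.REF else 1
        gts = np.asarray(rec.genotype.array())[:, :2]
        called = (gts >= 0).all(axis=1)
        dosage[:, j] = np.where(called, (gts == risk_idx).sum(axis=1), 0).astype(np.int8)
        missing[:, j] = ~called
    vcf.close()
    return DosageMatrix(
        individual_ids=samples,
        variant_rsids=tuple(panel.rsids),
        dosage=dosage,
        missing_mask=missing,
    )


def qc_strong_effect(
    matrix: DosageMatrix,
    panel: VariantPanel,
    or_threshold: float = 1.3,
    max_missing: float = 0.05,
) -> QCReport:
    """Flag strong-effect variants (oriented OR >= threshold) that exceed
    the tolerated missing fraction. The report passes iff none is flagged."""
    _check_alignment(matrix, panel)
    frac = matrix.missing_fraction()
    flags = []
    for j, v in enumerate(panel.variants):
        if frac[j] > max_missing:
            if v.odds_ratio >= or_threshold:
                flags.append(v.rsid)
            else:
                log.warning(
                    "variant %s missing in %.1f%% of individuals (OR %.2f below "
                    "strong-effect threshold; not flagged)",
                    v.rsid, 100 * frac[j], v.odds_ratio,
                )
    return QCReport(
        missing_fraction={v.rsid: float(frac[j]) for j, v in enumerate(panel.variants)},
        strong_effect_flags=tuple(flags),
        or_threshold=or_threshold,
        max_missing=max_missing,
    )


def compute_prs(
    matrix: DosageMatrix,
    panel: VariantPanel,
    missing_policy: MissingPolicy = "auto",
    thresholds: QuintileThresholds | None = None,
) -> list[PRSRecord]:
    """Compute per-individual weighted scores normalised by the mean weight.

    ``missing_policy`` governs masked cells: ``"impute_freq"`` substitutes
    the Hardy-Weinberg expectation ``2 * f_j`` (requires panel allele
    frequencies), ``"zero"`` counts them as zero risk alleles, ``"auto"``
    picks ``impute_freq`` when frequencies are available, else ``zero``
    with a warning. If ``thresholds`` is given, risk groups are attached.
    """
    _check_alignment(matrix, panel)
    w = panel.weights
    wbar = panel.mean_effect_weight
    if not wbar > 0:
        raise ValueError(f"panel mean effect weight must be > 0, got {wbar}")

    freqs = panel.risk_allele_freqs
    if missing_policy == "auto":
        if freqs is not None:
            missing_policy = "impute_freq"
        else:
            missing_policy = "zero"
            if matrix.missing_mask.any():
                log.warning("panel has no allele frequencies; missing dosages count as zero")
    if missing_policy == "impute_freq" and freqs is None:
        raise ValueError('missing_policy="impute_freq" requires panel risk allele frequencies')

    present = ~matrix.missing_mask
    observed = np.where(present, matrix.dosage, 0).astype(float)
    scores = observed @ w
    if missing_policy == "impute_freq":
        scores += matrix.missing_mask @ (2.0 * freqs * w)
    scores /= wbar

    n_missing = matrix.missing_mask.sum(axis=1)
    groups = assign_risk_groups(scores, thresholds) if thresholds is not None else None
    return [
        PRSRecord(
            individual_id=ind,
            prs=float(scores[i]),
            n_missing=int(n_missing[i]),
            risk_group=None if groups is None else int(groups[i]),
        )
        for i, ind in enumerate(matrix.individual_ids)
    ]


def derive_quintile_thresholds(reference_prs: Sequence[float]) -> QuintileThresholds:
    """Empirical 20/40/60/80th percentiles of a reference score set.

    Percentiles use linear interpolation between order statistics. At
    least five values are required, and degenerate references that give
    non-ascending cuts are rejected.
    """
    values = np.asarray(reference_prs, dtype=float)
    if values.size < 5:
        raise ValueError(f"need at least 5 reference scores, got {values.size}")
    cuts = np.percentile(values, [20, 40, 60, 80], method="linear")
    return QuintileThresholds(cuts=tuple(float(c) for c in cuts))


def assign_risk_group(prs: float, t: QuintileThresholds) -> int:
    """Map a score to its risk group 1-5 under left-closed boundaries."""
    return int(assign_risk_groups(np.asarray([prs], dtype=float), t)[0])


def assign_risk_groups(prs: np.ndarray, t: QuintileThresholds) -> np.ndarray:
    # side="left": a score equal to cut c_k stays in group k.
    return np.searchsorted(np.asarray(t.cuts), np.asarray(prs, dtype=float), side="left") + 1


def prs_frame(records: Iterable[PRSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.individual_id for r in records],
            "prs": [r.prs for r in records],
            "n_missing": [r.n_missing for r in records],
            "risk_group": [r.risk_group for r in records],
        }
    )


def write_prs_table(records: Iterable[PRSRecord], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        prs_frame(records).to_csv(fh, sep="\t", index=False)


def read_prs_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})


def _check_alignment(matrix: DosageMatrix, panel: VariantPanel) -> None:
    if list(matrix.variant_rsids) != panel.rsids:
        raise ValueError("dosage matrix variants are not aligned to the panel")
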