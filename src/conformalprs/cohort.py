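"""Synthetic case/control cohort generation.

Genotypes are drawn per variant under Hardy-Weinberg equilibrium
(dosage ~ Binomial(2, f)), and disease status from an additive logistic
liability on risk-allele dosages plus age and sex. The bundled preset
emulates the structure of a large AMD case/control resource: a
47-variant panel dominated by two strong loci, case scores shifted above
controls with substantial overlap, a training cohort of 1,667 cases /
1,148 controls and a validation cohort of 14,209 cases / 16,566 controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .panel import VariantPanel, curated_default_panel
from .prs import DosageMatrix

__all__ = [
    "DiseaseModel",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "sample_cohort",
    "iamdgc_disease_model",
    "make_iamdgc_preset",
    "PRESET_TRAIN_CASES",
    "PRESET_TRAIN_CONTROLS",
    "PRESET_VALID_CASES",
    "PRESET_VALID_CONTROLS",
    "write_vcf",
    "write_phenotypes",
    "read_phenotypes",
]

PRESET_TRAIN_CASES = 1_667
PRESET_TRAIN_CONTROLS = 1_148
PRESET_VALID_CASES = 14_209
PRESET_VALID_CONTROLS = 16_566


@dataclass(frozen=True)
class DiseaseModel:
    """Additive logistic generative model for disease status.

    The log-odds of being a case for individual *i* is::

        intercept + sum_j dosage_ij * beta_j
                  + age_effect * (age_i - age_ref)
                  + sex_effect * 1[sex_i == designated_sex]

    Ages are drawn from a normal truncated to [age_min, age_max]; sexes
    are balanced Bernoulli draws.
    """

    intercept: float
    variant_log_ors: np.ndarray
    risk_allele_freqs: np.ndarray
    age_effect: float = 0.04
    sex_effect: float = 0.1
    age_ref: float = 75.0
    age_mean: float = 74.0
    age_sd: float = 10.0
    age_min: float = 50.0
    age_max: float = 95.0
    designated_sex: str = "M"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.risk_allele_freqs, dtype=float)
        betas = np.asarray(self.variant_log_ors, dtype=float)
        if freqs.shape != betas.shape:
            raise ValueError("risk_allele_freqs and variant_log_ors must align")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValueError("risk allele frequencies must lie strictly inside (0, 1)")
        object.__setattr__(self, "variant_log_ors", betas)
        object.__setattr__(self, "risk_allele_freqs", freqs)

    def check_alignment(self, panel: VariantPanel) -> None:
        if self.variant_log_ors.shape[0] != len(panel):
            raise ValueError(
                f"model has {self.variant_log_ors.shape[0]} variant effects, "
                f"panel has {len(panel)}"
            )


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated genotype + phenotype cohort (reproducible from its seed)."""

    dosages: DosageMatrix
    phenotypes: pd.DataFrame  # columns: id, status, age, sex
    seed: int
    model: DiseaseModel

    def __post_init__(self) -> None:
        if len(self.phenotypes) != self.dosages.n_individuals:
            raise ValueError("phenotype rows must match dosage matrix individuals")
        if list(self.phenotypes["id"]) != list(self.dosages.individual_ids):
            raise ValueError("phenotype ids must align with dosage matrix ids")

    @property
    def n_cases(self) -> int:
        return int((self.phenotypes["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotypes["status"] == "control").sum())


def simulate_genotypes(
    panel: VariantPanel,
    n: int,
    freqs: np.ndarray | None = None,
    seed: int = 0,
    id_prefix: str = "S",
) -> DosageMatrix:
    """Draw an n x |panel| dosage matrix under Hardy-Weinberg equilibrium.

    Each cell is an independent Binomial(2, f_j) draw of risk-allele
    counts. ``freqs`` defaults to the panel's stored risk allele
    frequencies. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if freqs is None:
        freqs = panel.risk_allele_freqs
        if freqs is None:
            raise ValueError("panel carries no risk allele frequencies; pass freqs explicitly")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != len(panel):
        raise ValueError(f"freqs length {freqs.shape[0]} does not match panel size {len(panel)}")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, freqs, size=(n, len(panel))).astype(np.int8)
    ids = tuple(f"{id_prefix}{i:06d}" for i in range(n))
    return DosageMatrix(
        individual_ids=ids,
        variant_rsids=tuple(panel.rsids),
        dosage=dosage,
        missing_mask=np.zeros_like(dosage, dtype=bool),
    )


def simulate_phenotypes(
    dosages: DosageMatrix,
    panel: VariantPanel,
    model: DiseaseModel,
    seed: int = 0,
) -> SimulatedCohort:
    """Draw age, sex and Bernoulli disease status under the logistic model."""
    model.check_alignment(panel)
    if dosages.n_variants != len(panel):
        raise ValueError("dosage matrix is not aligned to the panel")
    rng = np.random.default_rng(seed)
    n = dosages.n_individuals

    a = (model.age_min - model.age_mean) / model.age_sd
    b = (model.age_max - model.age_mean) / model.age_sd
    ages = truncnorm.rvs(a, b, loc=model.age_mean, scale=model.age_sd, size=n, random_state=rng)
    ages = np.round(ages, 1)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")

    eta = (
        model.intercept
        + dosages.dosage.astype(float) @ model.variant_log_ors
        + model.age_effect * (ages - model.age_ref)
        + model.sex_effect * (sexes == model.designated_sex)
    )
    status = np.where(rng.random(n) < expit(eta), "case", "control")
    phenotypes = pd.DataFrame(
        {"id": list(dosages.individual_ids), "status": status, "age": ages, "sex": sexes}
    )
    return SimulatedCohort(dosages=dosages, phenotypes=phenotypes, seed=seed, model=model)


def sample_cohort(
    panel: VariantPanel,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int,
    id_prefix: str = "S",
) -> SimulatedCohort:
    """Simulate until exact case/control counts are met, then subsample.

    Individuals are drawn from the generative model in batches and the
    first ``n_cases`` cases and ``n_controls`` controls retained
    (stratified resampling), so label totals are exact while the
    within-class feature distributions remain those of the model.
    """
    seq = np.random.SeedSequence(seed)
    case_rows: list[int] = []
    control_rows: list[int] = []
    dosage_chunks: list[np.ndarray] = []
    pheno_chunks: list[pd.DataFrame] = []
    offset = 0
    batch = max(2_000, int(1.5 * (n_cases + n_controls)))
    for child in seq.spawn(64):
        g_seed, p_seed = child.spawn(2)
        dm = simulate_genotypes(
            panel, batch, model.risk_allele_freqs,
            seed=np.random.default_rng(g_seed).integers(2**31),
        )
        cohort = simulate_phenotypes(
            dm, panel, model, seed=np.random.default_rng(p_seed).integers(2**31)
        )
        dosage_chunks.append(dm.dosage)
        pheno_chunks.append(cohort.phenotypes)
        is_case = (cohort.phenotypes["status"] == "case").to_numpy()
        case_rows.extend((np.flatnonzero(is_case) + offset).tolist())
        control_rows.extend((np.flatnonzero(~is_case) + offset).tolist())
        offset += batch
        if len(case_rows) >= n_cases and len(control_rows) >= n_controls:
            break
    else:  # pragma: no cover - would need absurd prevalence
        raise RuntimeError("could not reach requested case/control counts")

    keep = np.sort(np.array(case_rows[:n_cases] + control_rows[:n_controls]))
    dosage = np.concatenate(dosage_chunks, axis=0)[keep]
    pheno = pd.concat(pheno_chunks, ignore_index=True).iloc[keep].reset_index(drop=True)
    ids = tuple(f"{id_prefix}{i:06d}" for i in range(len(keep)))
    pheno["id"] = list(ids)
    dm = DosageMatrix(
        individual_ids=ids,
        variant_rsids=tuple(panel.rsids),
        dosage=dosage,
        missing_mask=np.zeros_like(dosage, dtype=bool),
    )
    return SimulatedCohort(dosages=dm, phenotypes=pheno, seed=seed, model=model)


def iamdgc_disease_model(panel: VariantPanel, target_prevalence: float = 0.45) -> DiseaseModel:
    """The preset generative model: panel log-ORs as true effects.

    The intercept is set so the expected log-odds at mean genetic load,
    reference age and reference sex equals ``logit(target_prevalence)``.
    """
    freqs = panel.risk_allele_freqs
    if freqs is None:
        raise ValueError("panel must carry risk allele frequencies")
    betas = np.log([v.odds_ratio for v in panel.variants])
    intercept = float(logit(target_prevalence) - (2.0 * freqs * betas).sum())
    return DiseaseModel(intercept=intercept, variant_log_ors=betas, risk_allele_freqs=freqs)


def make_iamdgc_preset(seed: int) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Training and validation cohorts matching the reference study sizes.

    Returns (train, valid) with exactly 1,667 / 1,148 and
    14,209 / 16,566 cases / controls on the curated 47-variant panel.
    """
    panel = curated_default_panel()
    model = iamdgc_disease_model(panel)
    train_seed, valid_seed = (
        np.random.default_rng(np.random.SeedSequence(seed)).integers(2**31, size=2).tolist()
    )
    train = sample_cohort(
        panel, model, PRESET_TRAIN_CASES, PRESET_TRAIN_CONTROLS, seed=train_seed, id_prefix="T"
    )
    valid = sample_cohort(
        panel, model, PRESET_VALID_CASES, PRESET_VALID_CONTROLS, seed=valid_seed, id_prefix="V"
    )
    return train, valid


# ---------------------------------------------------------------------------
# I/O round-trip helpers


def write_vcf(dosages: DosageMatrix, panel: VariantPanel, path, extra_header: tuple[str, ...] = ()) -> None:
    """Write dosages as an uncompressed biallelic VCF (GT field only).

    Risk-allele counts are translated back to REF/ALT genotypes, so a
    risk allele on the REF strand yields the complementary ALT count.
    Records are emitted in (chrom, pos) order.
    """
    order = sorted(range(len(panel)), key=lambda j: (panel.variants[j].chrom, panel.variants[j].pos))
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(f"##{line}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.individual_ids)
            + "\n"
        )
        for j in order:
            v = panel.variants[j]
            alt_count = dosages.dosage[:, j].astype(int)
            if v.risk_allele == v.ref_allele:
                alt_count = 2 - alt_count
            cells = gt_strings[alt_count]
            cells = np.where(dosages.missing_mask[:, j], "./.", cells)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def write_phenotypes(phenotypes: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        phenotypes.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "status": str, "sex": str})
    required = {"id", "status", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {', '.join(sorted(missing))}")
    return df
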