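"""Risk-variant panel loading, curation and risk-allele orientation.

A panel is an ordered collection of biallelic variants, each carrying a
per-risk-allele odds ratio. Protective variants (OR < 1) are flipped to
risk orientation at load time so that downstream dosages always count
risk alleles and all effect weights are non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantPanel",
    "ExclusionList",
    "PANEL_COLUMNS",
    "orient_to_risk",
    "load_panel",
    "load_exclusions",
    "apply_exclusions",
    "default_panel",
    "default_exclusions",
    "curated_default_panel",
]

#: Required columns of a panel TSV, in canonical order.
PANEL_COLUMNS = ("rsid", "chrom", "pos", "ref", "alt", "risk_allele", "odds_ratio", "locus")

WeightScale = Literal["log", "or"]


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic panel variant with its per-allele effect.

    ``effect_weight`` is the additive-scale effect size used for PRS
    weighting: the natural log of the odds ratio by default, or the raw
    odds ratio when a panel is loaded with ``weight_scale="or"``.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    risk_allele: str
    odds_ratio: float
    effect_weight: float
    locus_name: str = ""
    risk_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError(f"{self.rsid}: odds_ratio must be > 0, got {self.odds_ratio}")
        if self.risk_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"{self.rsid}: risk allele {self.risk_allele!r} is neither "
                f"ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )
        if self.risk_allele_freq is not None and not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(f"{self.rsid}: risk_allele_freq must lie in (0, 1)")

    @property
    def other_allele(self) -> str:
        return self.alt_allele if self.risk_allele == self.ref_allele else self.ref_allele


def orient_to_risk(v: VariantRecord, weight_scale: WeightScale = "log") -> VariantRecord:
    """Return ``v`` oriented so its odds ratio is >= 1.

    Protective variants (OR < 1) have their risk allele swapped to the
    other allele and the OR replaced by its reciprocal; the stated risk
    allele frequency, if any, is complemented accordingly. Idempotent.
    """
    if v.odds_ratio < 1.0:
        freq = None if v.risk_allele_freq is None else 1.0 - v.risk_allele_freq
        v = replace(
            v,
            risk_allele=v.other_allele,
            odds_ratio=1.0 / v.odds_ratio,
            risk_allele_freq=freq,
            effect_weight=0.0,  # recomputed below
        )
    weight = math.log(v.odds_ratio) if weight_scale == "log" else v.odds_ratio
    return replace(v, effect_weight=weight)


@dataclass(frozen=True)
class VariantPanel:
    """An ordered, non-empty panel of risk-oriented variants."""

    variants: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("panel must contain at least one variant")
        seen: set[str] = set()
        for v in self.variants:
            if v.rsid in seen:
                raise ValueError(f"duplicate rsid in panel: {v.rsid}")
            seen.add(v.rsid)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.effect_weight for v in self.variants], dtype=float)

    @property
    def mean_effect_weight(self) -> float:
        """Arithmetic mean of the per-variant effect weights."""
        return float(self.weights.mean())

    @property
    def risk_allele_freqs(self) -> np.ndarray | None:
        """Per-variant risk allele frequencies, or None if any is unset."""
        freqs = [v.risk_allele_freq for v in self.variants]
        if any(f is None for f in freqs):
            return None
        return np.array(freqs, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": v.rsid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "risk_allele": v.risk_allele,
                "odds_ratio": v.odds_ratio,
                "effect_weight": v.effect_weight,
                "locus": v.locus_name,
                "risk_allele_freq": v.risk_allele_freq,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExclusionList:
    """rsids to drop from a panel, each with a free-text reason."""

    rsids: tuple[str, ...]
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("duplicate rsid in exclusion list")
        if self.reasons and len(self.reasons) != len(self.rsids):
            raise ValueError("reasons must align with rsids")


def load_panel(path, weight_scale: WeightScale = "log") -> VariantPanel:
    """Load a panel TSV and orient every variant to risk.

    The file must carry the columns ``rsid, chrom, pos, ref, alt,
    risk_allele, odds_ratio, locus`` (an optional ``risk_allele_freq``
    column is honoured). Raises ``ValueError`` naming the offending row
    on a missing column, a non-positive OR or a duplicate rsid.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str}, comment="#")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} is missing columns: {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        odds = float(row["odds_ratio"])
        if not odds > 0:
            raise ValueError(f"row {idx} ({row['rsid']}): odds_ratio must be > 0, got {odds}")
        freq = None
        if "risk_allele_freq" in df.columns and pd.notna(row["risk_allele_freq"]):
            freq = float(row["risk_allele_freq"])
        rec = VariantRecord(
            rsid=str(row["rsid"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]),
            risk_allele=str(row["risk_allele"]),
            odds_ratio=odds,
            effect_weight=0.0,
            locus_name="" if pd.isna(row["locus"]) else str(row["locus"]),
            risk_allele_freq=freq,
        )
        records.append(orient_to_risk(rec, weight_scale=weight_scale))
    return VariantPanel(variants=tuple(records))


def load_exclusions(path) -> ExclusionList:
    """Load an exclusion TSV with columns ``rsid, reason``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "rsid" not in df.columns:
        raise ValueError(f"exclusion file {path} is missing column: rsid")
    reasons = df["reason"].fillna("").tolist() if "reason" in df.columns else [""] * len(df)
    return ExclusionList(rsids=tuple(df["rsid"]), reasons=tuple(reasons))


def apply_exclusions(panel: VariantPanel, excl: ExclusionList) -> VariantPanel:
    """Drop excluded variants, leaving survivors untouched.

    Every excluded rsid must be present in the panel; an absent rsid is a
    hard error, since it signals a panel/exclusion-list mismatch. The
    panel mean effect weight is implicitly recomputed over survivors.
    """
    panel_ids = set(panel.rsids)
    absent = [r for r in excl.rsids if r not in panel_ids]
    if absent:
        raise ValueError(f"exclusion rsids not found in panel: {', '.join(absent)}")
    drop = set(excl.rsids)
    survivors = tuple(v for v in panel.variants if v.rsid not in drop)
    return VariantPanel(variants=survivors)


def _data_path(name: str):
    return resources.files("conformalprs.data").joinpath(name)


def default_panel(weight_scale: WeightScale = "log") -> VariantPanel:
    """The bundled 52-variant demonstration panel (pre-exclusion)."""
    with resources.as_file(_data_path("panel52.tsv")) as p:
        return load_panel(p, weight_scale=weight_scale)


def default_exclusions() -> ExclusionList:
    """The five low-coverage variants excluded from the bundled panel."""
    with resources.as_file(_data_path("exclusions.tsv")) as p:
        return load_exclusions(p)


def curated_default_panel(weight_scale: WeightScale = "log") -> VariantPanel:
    """Bundled panel after exclusions: the 47 variants actually scored."""
    return apply_exclusions(default_panel(weight_scale), default_exclusions())
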