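import math

import numpy as np
import pytest

from conformalprs.panel import VariantPanel, VariantRecord
from conformalprs.prs import DosageMatrix

BASES = ("A", "C", "G", "T")


def make_panel(odds_ratios, freqs=None, chrom="1", start_pos=1000):
    """Build a risk-oriented panel with the given (already >= 1) odds ratios."""
    records = []
    for j, orj in enumerate(odds_ratios):
        freq = None if freqs is None else float(freqs[j])
        records.append(
            VariantRecord(
                rsid=f"rs{j + 1}",
                chrom=chrom,
                pos=start_pos + j * 100,
                ref_allele="A",
                alt_allele="G",
                risk_allele="G",
                odds_ratio=float(orj),
                effect_weight=math.log(orj),
                locus_name=f"LOCUS{j + 1}",
                risk_allele_freq=freq,
            )
        )
    return VariantPanel(variants=tuple(records))


def panel_from_weights(weights, freqs=None):
    """Panel whose ln-OR effect weights equal ``weights`` exactly."""
    return make_panel([math.exp(w) for w in weights], freqs=freqs)


def make_matrix(dosage, missing=None, panel=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if missing is None:
        missing = np.zeros_like(dosage, dtype=bool)
    rsids = tuple(f"rs{j + 1}" for j in range(m)) if panel is None else tuple(panel.rsids)
    return DosageMatrix(
        individual_ids=tuple(f"I{i:04d}" for i in range(n)),
        variant_rsids=rsids,
        dosage=dosage,
        missing_mask=np.asarray(missing, dtype=bool),
    )


@pytest.fixture(scope="session")
def bundled_panel():
    from conformalprs.panel import default_panel

    return default_panel()


@pytest.fixture(scope="session")
def curated_panel():
    from conformalprs.panel import curated_default_panel

    return curated_default_panel()


@pytest.fixture(scope="session")
def small_cohort(curated_panel):
    """A 150-case / 150-control cohort under the preset disease model."""
    from conformalprs.cohort import iamdgc_disease_model, sample_cohort

    model = iamdgc_disease_model(curated_panel)
    return sample_cohort(curated_panel, model, 150, 150, seed=42)
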