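from __future__ import annotations

import pandas as pd
import pytest

from quartet_qc.variants import (
    BenchmarkSet,
    Genotype,
    QuartetVariantSet,
    VariantRecord,
    parse_genotype,
)


def rec(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    d5: str,
    d6: str,
    f7: str,
    m8: str,
) -> VariantRecord:
    """Build a record from genotype strings like '0/1' or './.'."""
    return VariantRecord(
        chrom,
        pos,
        ref,
        alt,
        {
            "D5": parse_genotype(d5),
            "D6": parse_genotype(d6),
            "F7": parse_genotype(f7),
            "M8": parse_genotype(m8),
        },
    )


def vset(records) -> QuartetVariantSet:
    return QuartetVariantSet(records=list(records))


@pytest.fixture
def concordant_het_site() -> VariantRecord:
    return rec("chr1", 100, "A", "G", "0/1", "0/1", "0/1", "0/0")


@pytest.fixture
def tiny_profile_frame() -> pd.DataFrame:
    """3 features x 12 columns (4 donors x 3 replicates), raw scale."""
    cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2, 3)]
    rows = {
        "G1": [100, 110, 90, 50, 55, 45, 200, 210, 190, 150, 140, 160],
        "G2": [10, 12, 11, 10, 11, 12, 9, 10, 11, 10, 12, 11],
        "G3": [500, 480, 520, 250, 260, 240, 100, 110, 90, 400, 420, 380],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(float)
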