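"""Quantitative-omics profile containers and TSV I/O.

A profile is a feature-by-sample abundance matrix for one batch, with
columns labelled ``<donor>_<replicate>`` (e.g. ``D5_1``) over the four
quartet donors, typically three technical replicates each.  Missing values
are encoded explicitly as NaN, never as zero; an optional switch coerces
zeros to missing on read for assays (commonly proteomics) that report
absent features as 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import DONORS

__all__ = [
    "PAIRS",
    "QuantProfile",
    "ReferenceRatioSet",
    "read_profile",
    "write_profile",
    "read_reference_ratios",
    "write_reference_ratios",
]

#: Donor pairs used for ratio-to-D6 reference comparisons.
PAIRS: tuple[str, str, str] = ("D5/D6", "F7/D6", "M8/D6")

_COLUMN_RE = re.compile(r"^(D5|D6|F7|M8)_(\d+)$")


def donor_of(column: str) -> str:
    m = _COLUMN_RE.match(column)
    if not m:
        raise ValueError(f"column {column!r} does not match <donor>_<replicate>")
    return m.group(1)


@dataclass
class QuantProfile:
    """Feature x (donor, replicate) abundance matrix for one batch.

    ``data`` holds nonnegative abundances (or log2 values when
    ``log_scale`` is True) with NaN for missing cells.
    """

    data: pd.DataFrame
    batch_id: str = "batch"
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate profile column labels")
        donors_seen = {donor_of(c) for c in self.data.columns}
        missing = set(DONORS) - donors_seen
        if missing:
            raise ValueError(f"profile lacks columns for donors: {sorted(missing)}")
        if not self.log_scale and (self.data.values < 0).any():
            raise ValueError("raw-scale abundances must be nonnegative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def donor_columns(self, donor: str) -> list[str]:
        return [c for c in self.data.columns if donor_of(c) == donor]

    def replicate_count(self, donor: str) -> int:
        return len(self.donor_columns(donor))

    def log2_matrix(self) -> pd.DataFrame:
        """The matrix on log2 scale (log2(x + 1) applied to raw values)."""
        if self.log_scale:
            return self.data
        return np.log2(self.data + 1.0)

    def raw_matrix(self) -> pd.DataFrame:
        """The matrix on raw scale (inverts log2(x + 1) when needed)."""
        if self.log_scale:
            return np.exp2(self.data) - 1.0
        return self.data


@dataclass
class ReferenceRatioSet:
    """Per-feature reference log2 ratios and differential-abundance flags.

    ``ratios`` and ``dam_flags`` are feature-indexed frames with one column
    per donor pair (D5/D6, F7/D6, M8/D6).  Flags mark the features the
    reference dataset calls differentially abundant for that pair.
    """

    ratios: pd.DataFrame
    dam_flags: pd.DataFrame

    def __post_init__(self) -> None:
        for frame, label in ((self.ratios, "ratios"), (self.dam_flags, "dam_flags")):
            missing = [p for p in PAIRS if p not in frame.columns]
            if missing:
                raise ValueError(f"{label} lacks pair columns {missing}")
        if not np.isfinite(self.ratios[list(PAIRS)].values).all():
            raise ValueError("reference ratios must be finite")
        if not self.dam_flags.index.equals(self.ratios.index):
            self.dam_flags = self.dam_flags.reindex(self.ratios.index, fill_value=False)
        self.dam_flags = self.dam_flags[list(PAIRS)].astype(bool)
        self.ratios = self.ratios[list(PAIRS)].astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.ratios.index)


def read_profile(
    path: str | Path,
    zeros_as_missing: bool = False,
    log_scale: bool = False,
    batch_id: str | None = None,
) -> QuantProfile:
    """Read a TSV profile (feature ids in the first column, then
    ``<donor>_<replicate>`` columns) into a :class:`QuantProfile`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in frame.columns:
        if not _COLUMN_RE.match(col):
            raise ValueError(
                f"{path}: column {col!r} does not match <donor>_<replicate>"
            )
    frame = frame.astype(float)
    if zeros_as_missing:
        frame = frame.where(frame != 0.0)
    return QuantProfile(
        data=frame,
        batch_id=batch_id or Path(path).stem,
        log_scale=log_scale,
    )


def write_profile(path: str | Path, profile: QuantProfile) -> None:
    profile.data.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_reference_ratios(
    ratios_path: str | Path, dam_flags_path: str | Path | None = None
) -> ReferenceRatioSet:
    """Read reference log2 ratios (and optionally DAM flags) from TSV.

    Both tables carry feature ids in the first column and one column per
    donor pair.  Without a flags file, no feature is flagged.
    """
    ratios = pd.read_csv(ratios_path, sep="\t", index_col=0)
    if dam_flags_path is not None:
        flags = pd.read_csv(dam_flags_path, sep="\t", index_col=0).astype(bool)
    else:
        flags = pd.DataFrame(False, index=ratios.index, columns=list(PAIRS))
    return ReferenceRatioSet(ratios=ratios, dam_flags=flags)


def write_reference_ratios(
    ratios_path: str | Path,
    reference: ReferenceRatioSet,
    dam_flags_path: str | Path | None = None,
) -> None:
    reference.ratios.to_csv(ratios_path, sep="\t", index_label="feature_id")
    if dam_flags_path is not None:
        reference.dam_flags.to_csv(dam_flags_path, sep="\t", index_label="feature_id")
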