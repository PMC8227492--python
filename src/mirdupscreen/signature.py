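"""miRNA expression signature: CPM normalization, log2 fold change,
up-regulation calls, heatmap Z-scores, and detection of precursors with both
duplex arms up-regulated.

The signature is a fold-change ranking, not a count-model differential
expression test: fold change compares arithmetic means of normalized values
between tumor and normal groups, stabilized by a pseudocount, and features
are called up-regulated by a strict threshold on log2 fold change
(default > 1.5). Down-stream duplex detection then asks which precursor
hairpins contribute both a ``-5p`` and a ``-3p`` mature strand to the
up-regulated list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SequenceRecord

UP_THRESHOLD_DEFAULT = 1.5
PSEUDOCOUNT_DEFAULT = 0.5


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA strand and its precursor/arm relationship."""

    mature_name: str
    precursor: str
    arm: str  # "5p" | "3p" | "unknown"
    sequence: SequenceRecord | None = None

    @classmethod
    def from_name(cls, mature_name: str, sequence: SequenceRecord | None = None) -> "MatureMiRNA":
        precursor, arm = parse_precursor(mature_name)
        return cls(mature_name, precursor, arm, sequence)


class FoldChangeTable:
    """Per-feature group means and log2 fold change (tumor vs normal)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"mean_tumor", "mean_normal", "log2fc"}
        if not required <= set(frame.columns):
            raise ValueError(f"fold-change frame needs columns {sorted(required)}")
        if not np.isfinite(frame["log2fc"]).all():
            raise ValueError("non-finite log2fc (pseudocount must be > 0)")
        self.frame = frame

    def log2fc(self, feature: str) -> float:
        return float(self.frame.loc[feature, "log2fc"])

    @property
    def feature_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def __len__(self) -> int:
        return len(self.frame)


def normalize_cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: scale each sample column to a total of 10^6."""
    totals = m.counts.sum(axis=0)
    zero = [s for s, t in zip(m.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    cpm = m.counts / totals * 1e6
    return pd.DataFrame(cpm, index=m.feature_ids, columns=m.sample_ids)


def log2_fold_change(
    normalized: pd.DataFrame,
    groups: Mapping[str, str],
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
) -> FoldChangeTable:
    """log2((mean_tumor + c) / (mean_normal + c)) on arithmetic group means."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    tumor = [s for s in normalized.columns if groups[s] == "tumor"]
    normal = [s for s in normalized.columns if groups[s] == "normal"]
    if not tumor or not normal:
        raise ValueError("both tumor and normal groups must be non-empty")
    mean_t = normalized[tumor].mean(axis=1)
    mean_n = normalized[normal].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_n + pseudocount))
    return FoldChangeTable(
        pd.DataFrame({"mean_tumor": mean_t, "mean_normal": mean_n, "log2fc": log2fc})
    )


def select_upregulated(fc: FoldChangeTable, threshold: float = UP_THRESHOLD_DEFAULT) -> list[str]:
    """Features with log2fc strictly above ``threshold``.

    Sorted by descending log2fc, ties broken lexicographically by id.
    """
    sub = fc.frame[fc.frame["log2fc"] > threshold]
    order = sorted(sub.index, key=lambda f: (-sub.loc[f, "log2fc"], f))
    return list(order)


def zscore_matrix(normalized: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Per-feature Z-scores across samples (mean 0, sd 1, ddof=1).

    This is the matrix behind the expression heat map; features with zero
    variance cannot be scaled and are rejected.
    """
    sub = normalized.loc[list(features)]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance features cannot be Z-scored: {flat}")
    return sub.sub(mu, axis=0).div(sd, axis=0)


def parse_precursor(mature_name: str) -> tuple[str, str]:
    """Split a mature name into (precursor stem, arm).

    ``hsa-miR-31-5p`` -> (``hsa-miR-31``, ``5p``); names without a -5p/-3p
    suffix map to themselves with arm ``unknown``.
    """
    for arm in ("5p", "3p"):
        suffix = f"-{arm}"
        if mature_name.endswith(suffix):
            return mature_name[: -len(suffix)], arm
    return mature_name, "unknown"


def detect_duplex_upregulated(up_features: Iterable[str]) -> list[str]:
    """Precursors contributing BOTH a 5p and a 3p arm to the up-regulated list.

    Returned sorted lexicographically.
    """
    arms: dict[str, set[str]] = {}
    for name in up_features:
        precursor, arm = parse_precursor(name)
        if arm != "unknown":
            arms.setdefault(precursor, set()).add(arm)
    return sorted(p for p, a in arms.items() if a == {"5p", "3p"})
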