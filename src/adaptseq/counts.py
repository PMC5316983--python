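"""Count matrices, depth normalization, fold changes and concordance.

The profiling readout is an integer matrix of variable-region sequences x
samples.  Depth normalization follows the library-profiling convention:
each count is divided by its sample's total valid count and multiplied by
the *global mean* — the arithmetic mean of per-sample totals in the batch —
so every normalized column sums to a common depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "NormalizedTable",
    "normalize_counts",
    "fold_change",
    "log2_fold_change",
    "replicate_concordance",
    "infer_pairs",
    "load_sample_sheet",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "index_i7", "cohort", "patient_id", "replicate")
COHORTS = ("cancer", "biopsy_negative", "healthy")


def _check_unique(values: Iterable[str], what: str) -> None:
    values = list(values)
    if len(values) != len(set(values)):
        raise ValueError(f"duplicate {what} in table")


@dataclass
class CountTable:
    """Integer sequences-x-samples matrix plus per-sample metadata.

    ``data`` is a DataFrame indexed by variable-region sequence with one
    column per sample_id; ``samples`` is indexed by sample_id and carries
    cohort / patient_id / replicate.
    """

    data: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sequences")
        _check_unique(self.data.columns, "sample_ids")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples.empty:
            self.samples = pd.DataFrame(index=self.data.columns)
        missing = set(self.data.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")
        self.samples = self.samples.loc[list(self.data.columns)]

    @property
    def sequences(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    @classmethod
    def from_sample_counts(
        cls, counts: Mapping[str, Mapping[str, int]], samples: pd.DataFrame | None = None
    ) -> "CountTable":
        """Build from {sample_id: {sequence: count}} (parser output)."""
        data = pd.DataFrame(counts).fillna(0).astype(np.int64)
        data = data.sort_index()
        return cls(data=data, samples=samples if samples is not None else pd.DataFrame())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sequence", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: pd.DataFrame | None = None
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("sequence")
        return cls(data=df.astype(np.int64), samples=samples if samples is not None else pd.DataFrame())


@dataclass
class NormalizedTable:
    """Depth-normalized counts; every column sums to ``global_mean``."""

    data: pd.DataFrame
    samples: pd.DataFrame
    global_mean: float

    @property
    def sequences(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "sequence", out.index)
        out.to_csv(path, sep="\t", index=False)


def normalize_counts(table: CountTable) -> NormalizedTable:
    """normalized[i, j] = counts[i, j] / total[j] * mean(totals).

    Raises on a zero-total sample, naming it.  Renormalizing the result
    leaves it unchanged (idempotent up to floating error).
    """
    totals = table.totals.astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    global_mean = float(totals.mean())
    data = table.data.astype(float) / totals * global_mean
    return NormalizedTable(data=data, samples=table.samples.copy(), global_mean=global_mean)


def fold_change(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-feature (mean_a + pi) / (mean_b + pi), direction preserved.

    Inputs are features-x-samples slices of a normalized table.  The
    default pseudocount of 1 normalized count guards sparse features
    without dominating typical depths.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold_change: empty group")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_a = a.mean(axis=1) if a.ndim == 2 else a
    mean_b = b.mean(axis=1) if b.ndim == 2 else b
    denom = mean_b + pseudocount
    if np.any(denom == 0):
        raise ValueError("fold_change: zero denominator with pseudocount 0")
    return (mean_a + pseudocount) / denom


def log2_fold_change(
    group_a, group_b, pseudocount: float = 1.0
) -> np.ndarray:
    """|threshold|-friendly companion: log2 of :func:`fold_change`."""
    return np.log2(fold_change(group_a, group_b, pseudocount=pseudocount))


def infer_pairs(
    samples: pd.DataFrame, max_inter_pairs: int | None = None
) -> list[tuple[str, str, str]]:
    """Derive (sample_a, sample_b, label) pairs from the sample sheet.

    intra: technical replicates of the same patient; inter: first-replicate
    samples of distinct patients (optionally capped).
    """
    if "patient_id" not in samples.columns:
        raise ValueError("sample sheet lacks a patient_id column")
    pairs: list[tuple[str, str, str]] = []
    for _, grp in samples.groupby("patient_id", sort=False):
        ids = list(grp.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j], "intra"))
    firsts = samples.groupby("patient_id", sort=False).head(1)
    ids = list(firsts.index)
    inter = [
        (ids[i], ids[j], "inter")
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    if max_inter_pairs is not None:
        inter = inter[:max_inter_pairs]
    return pairs + inter


def replicate_concordance(
    norm: NormalizedTable,
    pairs: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """Pearson r and r^2 per sample pair, labelled intra/inter.

    A pair with a constant vector gets r = NaN and constant=True rather
    than a fabricated value.  Requires >= 3 shared features.
    """
    if len(norm.data.index) < 3:
        raise ValueError("concordance needs >= 3 features")
    rows = []
    X = norm.data
    for a, b, label in pairs:
        xa = X[a].to_numpy(dtype=float)
        xb = X[b].to_numpy(dtype=float)
        constant = bool(np.ptp(xa) == 0 or np.ptp(xb) == 0)
        if constant:
            r = np.nan
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "label": label,
                "r": r,
                "r2": r * r if not np.isnan(r) else np.nan,
                "constant": constant,
            }
        )
    return pd.DataFrame(rows)


def concordance_summary(concordance: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of r grouped by the intra/inter label."""
    return (
        concordance.dropna(subset=["r"])
        .groupby("label")["r"]
        .agg(["count", "mean", "min", "max"])
        .reset_index()
    )


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the CSV sample sheet (sample_id,index_i7,cohort,patient_id,replicate)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample sheet has duplicate sample_ids")
    if df["index_i7"].duplicated().any():
        raise ValueError("sample sheet has duplicate i7 indices")
    return df.set_index("sample_id")
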