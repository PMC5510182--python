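"""Condition normalization and per-compound summarization of RGES.

A compound is typically profiled under many assay conditions (cell line,
dose, treatment duration), each yielding its own RGES.  Scores from
different conditions are not directly comparable: longer treatment and
higher concentration tend to produce stronger reversal.  This module

1. bins conditions into a 2x2 grid around the reference condition
   (10 uM, 24 h — the most common assay condition in L1000-style data),
2. estimates an additive offset per non-reference bin from compounds
   profiled in the same cell line under both the reference and the target
   condition,
3. weights each profile by how transcriptionally similar its cell line is
   to the tumours being targeted (mean rank correlation, max-normalized),
4. combines the offset-adjusted, weighted per-profile scores into one
   summarized RGES (sRGES) per compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

logger = logging.getLogger(__name__)

REFERENCE_DOSE_UM = 10.0
REFERENCE_TIME_H = 24.0
#: Minimum (compound, cell line) pairs supporting a bin before its estimated
#: offset is trusted; below this the offset falls back to 0.
DEFAULT_MIN_PAIRS = 10

SummaryStrategy = Literal["weighted", "best", "median", "mean"]


class ConditionBin(NamedTuple):
    """Dose/time class of an assay condition relative to the reference."""

    dose_class: str  # "low" (<10 uM) or "high" (>=10 uM)
    time_class: str  # "short" (<24 h) or "long" (>=24 h)


REFERENCE_BIN = ConditionBin("high", "long")
ALL_BINS = [
    ConditionBin(d, t) for d in ("low", "high") for t in ("short", "long")
]


def assign_bin(dose_um: float, time_h: float,
               reference_dose_um: float = REFERENCE_DOSE_UM,
               reference_time_h: float = REFERENCE_TIME_H) -> ConditionBin:
    """Classify a condition; boundary values fall on the reference side."""
    if dose_um < 0:
        raise DataError(f"negative dose: {dose_um}")
    if time_h <= 0:
        raise DataError(f"non-positive treatment time: {time_h}")
    return ConditionBin(
        "high" if dose_um >= reference_dose_um else "low",
        "long" if time_h >= reference_time_h else "short",
    )


def _with_bins(scores: pd.DataFrame,
               reference_dose_um: float = REFERENCE_DOSE_UM,
               reference_time_h: float = REFERENCE_TIME_H) -> pd.DataFrame:
    df = scores.copy()
    df["_bin"] = [
        assign_bin(d, t, reference_dose_um, reference_time_h)
        for d, t in zip(df["dose_um"], df["time_h"])
    ]
    return df


# ---------------------------------------------------------------------------
# condition offsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionOffsets:
    """Additive RGES adjustment toward the reference condition, per bin.

    ``offset[b]`` is the mean over qualifying (compound, cell line) pairs of
    (mean reference-bin RGES - mean bin-b RGES); adding it to a bin-b score
    estimates what the score would have been at the reference condition.  The
    reference bin's offset is identically 0.
    """

    offset: dict[ConditionBin, float]
    support: dict[ConditionBin, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", dict(self.offset))
        self.offset.setdefault(REFERENCE_BIN, 0.0)
        if self.offset[REFERENCE_BIN] != 0.0:
            raise DataError("reference-bin offset must be exactly 0")
        for b, v in self.offset.items():
            if not np.isfinite(v):
                raise DataError(f"non-finite offset for bin {b}")

    def __getitem__(self, b: ConditionBin) -> float:
        return self.offset.get(b, 0.0)

    @classmethod
    def zeros(cls) -> "ConditionOffsets":
        return cls({b: 0.0 for b in ALL_BINS}, {b: 0 for b in ALL_BINS})

    def save(self, path: str | Path) -> None:
        rows = [
            {"dose_class": b.dose_class, "time_class": b.time_class,
             "offset": self.offset.get(b, 0.0), "support": self.support.get(b, 0)}
            for b in ALL_BINS
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ConditionOffsets":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        offset = {ConditionBin(r.dose_class, r.time_class): float(r.offset)
                  for r in df.itertuples()}
        support = {ConditionBin(r.dose_class, r.time_class): int(r.support)
                   for r in df.itertuples()}
        return cls(offset, support)


def estimate_offsets(scores: pd.DataFrame,
                     min_pairs: int = DEFAULT_MIN_PAIRS,
                     reference_dose_um: float = REFERENCE_DOSE_UM,
                     reference_time_h: float = REFERENCE_TIME_H) -> ConditionOffsets:
    """Estimate per-bin offsets from within-cell-line paired comparisons.

    Only compounds profiled in the same cell line under both the reference
    condition and the target bin contribute; each such (compound, cell line)
    pair contributes one paired difference of bin-mean scores.  Bins with
    fewer than ``min_pairs`` supporting pairs keep offset 0 with a warning.

    ``scores`` is a per-profile table as produced by
    :func:`rges.core.batch_score` (columns compound_id, cell_line, dose_um,
    time_h, rges).
    """
    df = _with_bins(scores, reference_dose_um, reference_time_h)
    ref_means = (
        df[df["_bin"] == REFERENCE_BIN]
        .groupby(["compound_id", "cell_line"])["rges"].mean()
    )
    offsets: dict[ConditionBin, float] = {REFERENCE_BIN: 0.0}
    support: dict[ConditionBin, int] = {REFERENCE_BIN: int((df["_bin"] == REFERENCE_BIN).sum())}
    any_pairs = False
    for b in ALL_BINS:
        if b == REFERENCE_BIN:
            continue
        bin_means = (
            df[df["_bin"] == b]
            .groupby(["compound_id", "cell_line"])["rges"].mean()
        )
        common = ref_means.index.intersection(bin_means.index)
        support[b] = len(common)
        if len(common) == 0:
            offsets[b] = 0.0
            continue
        any_pairs = True
        diffs = ref_means[common] - bin_means[common]
        if len(common) < min_pairs:
            logger.warning(
                "bin %s: only %d paired (compound, cell line) observations "
                "(< %d); offset forced to 0", b, len(common), min_pairs,
            )
            offsets[b] = 0.0
        else:
            offsets[b] = float(diffs.mean())
    if not any_pairs:
        raise DataError(
            "no (compound, cell line) pair spans the reference and a target "
            "condition; use ConditionOffsets.zeros() to skip normalization"
        )
    return ConditionOffsets(offsets, support)


# ---------------------------------------------------------------------------
# cell-line weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellWeightTable:
    """Per-cell-line weights from cell-tumour transcriptional similarity.

    ``raw_cor`` holds the mean rank correlation between each cell line and
    the individual tumours; weights are the correlations clamped at 0 and
    divided by the maximum, so weights live in [0, 1] with max exactly 1.
    """

    weight: dict[str, float]
    raw_cor: dict[str, float]

    def __post_init__(self) -> None:
        if self.weight:
            wmax = max(self.weight.values())
            if not np.isclose(wmax, 1.0):
                raise DataError(f"max weight must be 1, got {wmax}")
            if min(self.weight.values()) < 0:
                raise DataError("negative weight")

    def __getitem__(self, cell_line: str) -> float:
        return self.weight[cell_line]

    def __contains__(self, cell_line: str) -> bool:
        return cell_line in self.weight

    def save(self, path: str | Path) -> None:
        rows = [{"cell_line": c, "weight": self.weight[c],
                 "raw_cor": self.raw_cor.get(c, np.nan)}
                for c in sorted(self.weight)]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CellWeightTable":
        df = pd.read_csv(path, sep="\t", dtype={"cell_line": str}, float_precision="round_trip")
        return cls({r.cell_line: float(r.weight) for r in df.itertuples()},
                   {r.cell_line: float(r.raw_cor) for r in df.itertuples()})


def compute_cell_weights(cell_expr: pd.DataFrame, tumour_expr: pd.DataFrame,
                         method: Literal["spearman"] = "spearman") -> CellWeightTable:
    """Weight cell lines by mean rank correlation to individual tumours.

    Both inputs are genes x samples matrices; correlations use the shared
    genes only.  Negative mean correlations clamp to weight 0; the largest
    (clamped) correlation normalizes to weight 1.
    """
    if method != "spearman":
        raise ValueError(f"unsupported correlation method {method!r}")
    shared = cell_expr.index.intersection(tumour_expr.index)
    if len(shared) < 3:
        raise DataError(
            f"only {len(shared)} genes shared between cell-line and tumour "
            f"matrices (need >= 3)"
        )
    if tumour_expr.shape[1] < 1:
        raise DataError("tumour matrix has no samples")
    cells = cell_expr.loc[shared].to_numpy(dtype=float)
    tumours = tumour_expr.loc[shared].to_numpy(dtype=float)
    # one spearman per (cell, tumour) pair via ranked pearson, vectorized
    cr = sps.rankdata(cells, axis=0)
    tr = sps.rankdata(tumours, axis=0)
    cr = (cr - cr.mean(axis=0)) / cr.std(axis=0)
    tr = (tr - tr.mean(axis=0)) / tr.std(axis=0)
    cor = cr.T @ tr / len(shared)  # n_cells x n_tumours
    raw = {str(c): float(cor[i].mean()) for i, c in enumerate(cell_expr.columns)}
    clamped = {c: max(v, 0.0) for c, v in raw.items()}
    top = max(clamped.values())
    if top <= 0:
        raise DataError("all cell-tumour correlations are <= 0; weights undefined")
    n_clamped = sum(1 for v in raw.values() if v < 0)
    if n_clamped:
        logger.info("%d cell line(s) with negative tumour correlation clamped "
                    "to weight 0", n_clamped)
    return CellWeightTable({c: v / top for c, v in clamped.items()}, raw)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def summarize_srges(scores: pd.DataFrame,
                    offsets: ConditionOffsets | None = None,
                    weights: CellWeightTable | None = None,
                    strategy: SummaryStrategy = "weighted",
                    reference_dose_um: float = REFERENCE_DOSE_UM,
                    reference_time_h: float = REFERENCE_TIME_H) -> pd.DataFrame:
    """Summarize per-profile scores into one sRGES per compound.

    The default ``weighted`` strategy computes, per compound,

        sRGES = sum_i w(cell_i) * (RGES_i + offset[bin_i]) / sum_i w(cell_i)

    over the compound's profiles.  Profiles in cell lines missing from the
    weight table receive the mean available weight (with a warning); if all
    weights for a compound are 0 the unweighted mean of adjusted scores is
    used.  The alternative strategies ``best`` (minimum), ``median`` and
    ``mean`` summarize the *raw* per-profile scores and exist for
    benchmarking.

    Returns a table ``compound_id  srges  n_profiles  n_cell_lines`` sorted
    ascending by srges (most strongly reversing compounds first).
    """
    if scores.empty:
        raise DataError("empty score table")
    if offsets is None:
        offsets = ConditionOffsets.zeros()
    df = _with_bins(scores, reference_dose_um, reference_time_h)
    df["_adj"] = df["rges"] + [offsets[b] for b in df["_bin"]]

    if weights is not None and len(weights.weight):
        mean_w = float(np.mean(list(weights.weight.values())))
        known = df["cell_line"].map(weights.weight)
        n_unknown = int(known.isna().sum())
        if n_unknown:
            logger.warning(
                "%d profile(s) in cell lines absent from the weight table; "
                "using the mean available weight %.3f", n_unknown, mean_w,
            )
        df["_w"] = known.fillna(mean_w)
    else:
        df["_w"] = 1.0

    rows = []
    for compound, grp in df.groupby("compound_id", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            logger.warning("compound %s has no profiles; excluded", compound)
            continue
        if strategy == "weighted":
            wsum = float(grp["_w"].sum())
            if wsum == 0:
                logger.warning(
                    "compound %s: all weights are 0; falling back to "
                    "unweighted mean", compound,
                )
                srges = float(grp["_adj"].mean())
            else:
                srges = float((grp["_w"] * grp["_adj"]).sum() / wsum)
        elif strategy == "best":
            srges = float(grp["rges"].min())
        elif strategy == "median":
            srges = float(grp["rges"].median())
        elif strategy == "mean":
            srges = float(grp["rges"].mean())
        else:
            raise ValueError(f"unknown summary strategy {strategy!r}")
        rows.append({
            "compound_id": str(compound),
            "srges": srges,
            "n_profiles": int(len(grp)),
            "n_cell_lines": int(grp["cell_line"].nunique()),
        })
    out = pd.DataFrame(rows, columns=["compound_id", "srges", "n_profiles",
                                      "n_cell_lines"])
    return (out.sort_values(["srges", "compound_id"], kind="mergesort")
               .reset_index(drop=True))


def save_srges(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
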