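"""Identification of disease genes specifically reversed by effective drugs.

Compounds are split into an effective (median IC50 < 10 uM) and an
ineffective (median IC50 >= 10 uM) group.  Each compound is reduced to one
representative profile (the one carrying its median RGES), and each
disease-signature gene's normalized rank position (rank/n, rank 1 = most
upregulated so position 1/n = top of the list) is compared between groups
with a one-sided Mann-Whitney-Wilcoxon test:

* disease-UPregulated genes are "reversed" when effective compounds push
  them toward the BOTTOM of the ranked list — i.e. their normalized
  positions are stochastically GREATER in the effective group;
* disease-DOWNregulated genes are reversed when effective compounds pull
  them toward the TOP — positions stochastically smaller.

This directionality is the most error-prone sign in the pipeline; it
follows from the rank-1-at-the-top convention used throughout the package.
P values are Benjamini-Hochberg adjusted across all tested genes and genes
with adjusted P below 0.25 are flagged.  A leave-one-compound-out (LOCO)
sweep marks as *robust* only the genes flagged in every trial.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ProfileMatrix, rank_profile
from .errors import DataError
from .signatures import DiseaseSignature

logger = logging.getLogger(__name__)

DEFAULT_EFFECTIVE_THRESHOLD_UM = 10.0
DEFAULT_ALPHA = 0.25
#: Total group size above which the MWW test switches from exact
#: enumeration to the tie-corrected normal approximation.
EXACT_TEST_MAX_N = 20

RESULT_COLUMNS = ["gene", "direction", "u_stat", "p", "padj", "robust"]


# ---------------------------------------------------------------------------
# efficacy summarization
# ---------------------------------------------------------------------------

def lower_median(values) -> float:
    """Median taking the lower of the two middle values for even counts.

    Fixed (rather than the interpolated midpoint) so that for even counts
    the summary is always an observed value and results are bit-reproducible.
    """
    s = sorted(values)
    if not s:
        raise ValueError("median of empty sequence")
    return s[(len(s) - 1) // 2]


def load_efficacy(path: str | Path) -> pd.DataFrame:
    """Read an efficacy table: TSV ``compound_id  cell_line  ic50_um``."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "cell_line": str}, float_precision="round_trip")
    missing = {"compound_id", "ic50_um"} - set(df.columns)
    if missing:
        raise DataError(f"efficacy table {path} lacks column(s): {sorted(missing)}")
    return df


def summarize_efficacy(efficacy: pd.DataFrame,
                       threshold_um: float = DEFAULT_EFFECTIVE_THRESHOLD_UM,
                       ) -> dict[str, str]:
    """Label each compound effective/ineffective from its median IC50.

    Multiple IC50 measurements per compound are summarized by the
    lower-middle median; a compound is *effective* when that median is
    strictly below ``threshold_um`` and *ineffective* otherwise.
    """
    if (efficacy["ic50_um"] <= 0).any():
        bad = efficacy.loc[efficacy["ic50_um"] <= 0].iloc[0]
        raise DataError(
            f"non-positive IC50 {bad['ic50_um']} for compound "
            f"{bad['compound_id']!r}"
        )
    labels = {}
    for compound, grp in efficacy.groupby("compound_id", sort=True):
        med = lower_median(grp["ic50_um"].tolist())
        labels[str(compound)] = "effective" if med < threshold_um else "ineffective"
    return labels


# ---------------------------------------------------------------------------
# representative profiles and normalized positions
# ---------------------------------------------------------------------------

def select_representative_profile(scores: pd.DataFrame) -> str:
    """Pick the profile carrying a compound's median RGES.

    For even counts the profile with the lower of the two middle values is
    chosen; exact RGES ties break by ascending profile_id.
    """
    if scores.empty:
        raise DataError("no profiles to choose a representative from")
    ordered = sorted(zip(scores["rges"], scores["profile_id"].astype(str)))
    return ordered[(len(ordered) - 1) // 2][1]


def representative_profiles(scores: pd.DataFrame) -> dict[str, str]:
    """Map each compound to its representative (median-RGES) profile."""
    return {
        str(compound): select_representative_profile(grp)
        for compound, grp in scores.groupby("compound_id", sort=True)
    }


def normalized_positions(matrix: ProfileMatrix,
                         representatives: Mapping[str, str],
                         signature: DiseaseSignature) -> pd.DataFrame:
    """Signature-gene rank positions, scaled to (0, 1], per compound.

    Entry (g, c) is rank(g in c's representative profile) / n with rank 1 =
    most upregulated, so small values mean the gene sits at the top of the
    list.  Signature genes absent from the universe are dropped with a
    warning.
    """
    genes = [g for g in signature.universe.genes if g in signature.genes]
    missing = signature.genes - set(genes)
    if missing:
        logger.warning("%d signature gene(s) absent from universe dropped: %s",
                       len(missing), sorted(missing)[:5])
    if not genes:
        raise DataError("no signature genes present in the universe")
    cols = {}
    for compound in sorted(representatives):
        ranked = rank_profile(matrix.profile(representatives[compound]))
        cols[compound] = ranked.positions[genes].to_numpy(dtype=float) / ranked.n
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# the reversal test
# ---------------------------------------------------------------------------

def _mww_one_sided(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """One-sided MWW of x vs y; exact for small samples, else tie-corrected
    normal approximation."""
    method = "exact" if (len(x) + len(y) <= EXACT_TEST_MAX_N
                         and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
                         ) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _split_groups(positions: pd.DataFrame, labels: Mapping[str, str]
                  ) -> tuple[list[str], list[str]]:
    eff = [c for c in positions.columns if labels.get(c) == "effective"]
    ineff = [c for c in positions.columns if labels.get(c) == "ineffective"]
    unlabeled = [c for c in positions.columns if c not in labels]
    if unlabeled:
        logger.info("%d compound(s) without efficacy labels excluded from the "
                    "reversal test", len(unlabeled))
    return eff, ineff


def test_reversal(positions: pd.DataFrame, labels: Mapping[str, str],
                  signature: DiseaseSignature,
                  alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """One-sided MWW reversal test per signature gene, BH-adjusted.

    ``positions`` is the gene x compound matrix from
    :func:`normalized_positions`.  Returns ``gene direction u_stat p padj
    robust`` with ``robust`` left False (set by
    :func:`loco_reversal_genes`) and a boolean ``reversed`` column flagging
    padj < alpha.
    """
    eff, ineff = _split_groups(positions, labels)
    if len(eff) < 2 or len(ineff) < 2:
        raise DataError(
            f"need >= 2 compounds per group, got {len(eff)} effective / "
            f"{len(ineff)} ineffective"
        )
    rows = []
    for gene in positions.index:
        direction = signature.direction(gene)
        x = positions.loc[gene, eff].to_numpy(dtype=float)
        y = positions.loc[gene, ineff].to_numpy(dtype=float)
        # up genes: reversal pushes them DOWN the list = larger positions in
        # the effective group; down genes: the mirror image
        alternative = "greater" if direction == "up" else "less"
        u, p = _mww_one_sided(x, y, alternative)
        rows.append({"gene": gene, "direction": direction, "u_stat": u, "p": p})
    out = pd.DataFrame(rows)
    out["padj"] = sps.false_discovery_control(out["p"].to_numpy(), method="bh")
    out["reversed"] = out["padj"] < alpha
    out["robust"] = False
    return out


def loco_reversal_genes(positions: pd.DataFrame, labels: Mapping[str, str],
                        signature: DiseaseSignature,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Leave-one-compound-out robustness sweep of the reversal test.

    Runs :func:`test_reversal` on the full compound set and once with each
    labeled compound (from either group) removed; a gene is *robust* when
    flagged (padj < alpha) in every trial.  The returned statistics are the
    full-set ones with the robust flag filled in, so robust genes are always
    a subset of the full-set significant genes.
    """
    eff, ineff = _split_groups(positions, labels)
    if len(eff) < 3 or len(ineff) < 3:
        raise DataError(
            f"leave-one-compound-out needs >= 3 compounds per group, got "
            f"{len(eff)} effective / {len(ineff)} ineffective"
        )
    full = test_reversal(positions, labels, signature, alpha=alpha)
    robust = set(full.loc[full["reversed"], "gene"])
    for leave_out in eff + ineff:
        if not robust:
            break
        sub = positions.drop(columns=leave_out)
        trial = test_reversal(sub, labels, signature, alpha=alpha)
        robust &= set(trial.loc[trial["reversed"], "gene"])
    full["robust"] = full["gene"].isin(robust)
    n_full = int(full["reversed"].sum())
    logger.info("reversal genes: %d significant in the full set, %d robust "
                "across %d LOCO trials", n_full, len(robust), len(eff) + len(ineff))
    return full


def find_reversal_genes(matrix: ProfileMatrix, signature: DiseaseSignature,
                        scores: pd.DataFrame, efficacy: pd.DataFrame,
                        alpha: float = DEFAULT_ALPHA,
                        threshold_um: float = DEFAULT_EFFECTIVE_THRESHOLD_UM,
                        loco: bool = True) -> pd.DataFrame:
    """End-to-end reversal-gene discovery from scored profiles.

    Labels compounds from the efficacy table, reduces each labeled compound
    to its median-RGES representative profile, builds the normalized
    position matrix and runs the (optionally LOCO-robust) reversal test.
    """
    labels = summarize_efficacy(efficacy, threshold_um=threshold_um)
    labeled = scores[scores["compound_id"].isin(labels)]
    if labeled.empty:
        raise DataError("no scored profiles belong to compounds with efficacy data")
    reps = representative_profiles(labeled)
    positions = normalized_positions(matrix, reps, signature)
    if loco:
        return loco_reversal_genes(positions, labels, signature, alpha=alpha)
    return test_reversal(positions, labels, signature, alpha=alpha)


def save_reversal(result: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RESULT_COLUMNS if c in result.columns]
    result[cols].to_csv(path, sep="\t", index=False)
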