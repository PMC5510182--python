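"""Reverse gene expression scoring of drug perturbation profiles.

Each drug profile is a vector of differential-expression values over the
landmark-gene universe.  Genes are ranked by value, rank 1 being the most
upregulated.  For each direction of a disease signature a Kolmogorov–
Smirnov-type enrichment score measures whether the signature genes pile up
at the top or the bottom of the ranked list:

    a = max_j ( j/m - V(j)/n )        b = max_j ( V(j)/n - (j-1)/m )

with V the ascending positions of the m signature genes among the n ranked
genes, and es = a if a > b else -b.  The reverse gene expression score is

    RGES = es_up - es_down

with no zero-clamping when the two components share a sign: a strongly
negative RGES means the profile pushes disease-upregulated genes toward the
bottom of the list and disease-downregulated genes toward the top, i.e. it
reverses the disease signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .signatures import DiseaseSignature, GeneUniverse

logger = logging.getLogger(__name__)

#: Minimum signature genes per direction that must be present in the
#: universe for an RGES to be reported.
DEFAULT_MIN_OVERLAP = 3

#: Columns of the per-profile score table emitted by :func:`batch_score`.
SCORE_COLUMNS = [
    "profile_id", "compound_id", "cell_line", "dose_um", "time_h",
    "es_up", "es_down", "rges", "m_up", "m_down",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileMeta:
    """Assay condition metadata for one perturbation profile."""

    compound_id: str
    cell_line: str
    dose_um: float
    time_h: float
    quality_flag: bool

    def __post_init__(self) -> None:
        if self.dose_um < 0:
            raise DataError(f"negative dose: {self.dose_um}")
        if self.time_h <= 0:
            raise DataError(f"non-positive treatment time: {self.time_h}")


@dataclass(frozen=True)
class DrugProfile:
    """One profile: differential-expression values over the full universe."""

    profile_id: str
    values: pd.Series  # indexed by gene, covering the universe exactly
    meta: ProfileMeta


class ProfileMatrix:
    """A genes x profiles value matrix plus per-profile metadata.

    ``values`` is indexed by gene (the universe, in order); ``meta`` is
    indexed by profile_id with columns compound_id, cell_line, dose_um,
    time_h, quality_flag.
    """

    def __init__(self, universe: GeneUniverse, values: pd.DataFrame, meta: pd.DataFrame):
        if values.shape[1] == 0:
            raise DataError("profile matrix has no profiles")
        if list(values.index) != list(universe.genes):
            got, want = set(values.index), set(universe.genes)
            if got != want:
                raise DataError(
                    f"profile matrix genes do not match universe "
                    f"({len(want - got)} missing, {len(got - want)} extra)"
                )
            values = values.reindex(universe.genes)
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise DataError(f"duplicate profile_id {dup!r}")
        missing_meta = [p for p in values.columns if p not in meta.index]
        if missing_meta:
            raise DataError(f"profiles without metadata: {missing_meta[:5]}")
        self.universe = universe
        self.values = values
        self.values.index.name = "gene"
        self.meta = meta.loc[values.columns]
        self.meta.index.name = "profile_id"

    @property
    def profile_ids(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return self.values.shape[1]

    def profile(self, profile_id: str) -> DrugProfile:
        m = self.meta.loc[profile_id]
        return DrugProfile(
            profile_id,
            self.values[profile_id],
            ProfileMeta(
                str(m["compound_id"]), str(m["cell_line"]),
                float(m["dose_um"]), float(m["time_h"]), bool(m["quality_flag"]),
            ),
        )

    def __iter__(self) -> Iterator[DrugProfile]:
        for pid in self.profile_ids:
            yield self.profile(pid)

    # -- serialization ------------------------------------------------------

    def save(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        out = self.meta.copy()
        out["quality_flag"] = out["quality_flag"].astype(int)
        out.to_csv(meta_path, sep="\t", index_label="profile_id")

    @classmethod
    def load(cls, values_path: str | Path, meta_path: str | Path,
             universe: GeneUniverse | None = None) -> "ProfileMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="gene", float_precision="round_trip")
        values.index = values.index.astype(str)
        meta = load_profile_meta(meta_path)
        if universe is None:
            universe = GeneUniverse.from_iterable(values.index)
        return cls(universe, values, meta)


def load_profile_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="profile_id",
                       dtype={"compound_id": str, "cell_line": str}, float_precision="round_trip")
    meta.index = meta.index.astype(str)
    required = {"compound_id", "cell_line", "dose_um", "time_h", "quality_flag"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata {path} lacks column(s): {sorted(missing)}")
    meta["quality_flag"] = meta["quality_flag"].astype(bool)
    return meta


def read_gct(path: str | Path,
             meta_fields: dict[str, str] | None = None) -> ProfileMatrix:
    """Read a GCT v1.3 text matrix into a :class:`ProfileMatrix`.

    The column-annotation rows supply the condition metadata.  ``meta_fields``
    maps our metadata names to the annotation row names in the file; defaults
    follow common L1000 conventions (pert_id, cell_id, pert_dose, pert_time,
    is_gold).
    """
    fields = {
        "compound_id": "pert_id", "cell_line": "cell_id", "dose_um": "pert_dose",
        "time_h": "pert_time", "quality_flag": "is_gold",
    }
    if meta_fields:
        fields.update(meta_fields)

    with open(path) as fh:
        version = fh.readline().strip()
        if version not in {"#1.3", "#1.2"}:
            raise DataError(f"{path}: not a GCT file (first line {version!r})")
        dims = fh.readline().split()
        if version == "#1.2":
            nrow, ncol, nrmeta, ncmeta = int(dims[0]), int(dims[1]), 0, 0
        else:
            nrow, ncol, nrmeta, ncmeta = (int(x) for x in dims[:4])
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1 + nrmeta:]
        if len(col_ids) != ncol:
            raise DataError(f"{path}: header declares {len(col_ids)} profiles, "
                            f"expected {ncol}")
        col_meta: dict[str, list[str]] = {}
        for _ in range(ncmeta):
            parts = fh.readline().rstrip("\n").split("\t")
            col_meta[parts[0]] = parts[1 + nrmeta:]
        genes, data = [], []
        for _ in range(nrow):
            parts = fh.readline().rstrip("\n").split("\t")
            genes.append(parts[0])
            data.append([float(x) for x in parts[1 + nrmeta:]])

    values = pd.DataFrame(data, index=genes, columns=col_ids)
    meta_rows = {}
    for pid_i, pid in enumerate(col_ids):
        def get(our_name: str, default=None):
            row = col_meta.get(fields[our_name])
            if row is None:
                if default is None:
                    raise DataError(
                        f"{path}: missing column annotation "
                        f"{fields[our_name]!r} needed for {our_name}"
                    )
                return default
            return row[pid_i]
        meta_rows[pid] = {
            "compound_id": str(get("compound_id")),
            "cell_line": str(get("cell_line")),
            "dose_um": float(get("dose_um")),
            "time_h": float(get("time_h")),
            "quality_flag": str(get("quality_flag", "1")) in {"1", "True", "true"},
        }
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "profile_id"
    universe = GeneUniverse.from_iterable(genes)
    return ProfileMatrix(universe, values, meta)


# ---------------------------------------------------------------------------
# ranking and enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedProfile:
    """Gene -> rank map for one profile; rank 1 = most upregulated."""

    positions: pd.Series  # int ranks 1..n indexed by gene
    n: int

    def rank_of(self, gene: str) -> int:
        return int(self.positions[gene])


def rank_profile(profile: DrugProfile) -> RankedProfile:
    """Rank genes by differential-expression value, descending.

    Rank 1 is the most upregulated gene.  Ties are broken by ascending gene
    identifier so the ranking is deterministic.
    """
    values = profile.values
    arr = values.to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        gene = values.index[int(np.flatnonzero(bad)[0])]
        raise DataError(
            f"profile {profile.profile_id!r}: non-finite value for gene {gene!r}"
        )
    genes = values.index.to_numpy(dtype=object)
    # lexsort: primary key last -> sort by -value, then gene id ascending
    order = np.lexsort((genes, -arr))
    ranks = np.empty(len(arr), dtype=np.int64)
    ranks[order] = np.arange(1, len(arr) + 1)
    return RankedProfile(pd.Series(ranks, index=values.index), len(arr))


def enrichment_score(ranked: RankedProfile, geneset: frozenset[str] | set[str]) -> float:
    """KS-style enrichment of a gene set in a ranked profile.

    Returns ``a`` if ``a > b`` else ``-b`` where a and b are the two one-sided
    maxima of the running deviation between the set's position distribution
    and uniform.  Positive values mean the set sits near the top of the list
    (upregulated), negative near the bottom.
    """
    if not geneset:
        raise DataError("empty gene set")
    missing = [g for g in geneset if g not in ranked.positions.index]
    if missing:
        raise DataError(f"gene set members outside universe: {sorted(missing)[:5]}")
    v = np.sort(ranked.positions[list(geneset)].to_numpy(dtype=float))
    m, n = len(v), ranked.n
    j = np.arange(1, m + 1, dtype=float)
    a = np.max(j / m - v / n)
    b = np.max(v / n - (j - 1) / m)
    return float(a) if a > b else float(-b)


@dataclass(frozen=True)
class RGESRecord:
    """Reversal score of one profile against one disease signature."""

    profile_id: str
    es_up: float
    es_down: float
    rges: float
    m_up: int
    m_down: int


def compute_rges(profile: DrugProfile, signature: DiseaseSignature,
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> RGESRecord:
    """Score one profile: RGES = es_up - es_down.

    Signature genes absent from the profile's universe are dropped per
    direction (with a logged count); if fewer than ``min_overlap`` genes
    remain in either direction the score is refused.
    """
    ranked = rank_profile(profile)
    universe_genes = set(profile.values.index)
    up = signature.up & universe_genes
    down = signature.down & universe_genes
    for name, full, kept in (("up", signature.up, up), ("down", signature.down, down)):
        if len(kept) < len(full):
            logger.debug("profile %s: %d %s-genes outside universe dropped",
                         profile.profile_id, len(full) - len(kept), name)
        if len(kept) < min_overlap:
            raise DataError(
                f"profile {profile.profile_id!r}: only {len(kept)} {name}-genes "
                f"overlap the universe (need >= {min_overlap}); missing: "
                f"{sorted(full - kept)[:10]}"
            )
    es_up = enrichment_score(ranked, up)
    es_down = enrichment_score(ranked, down)
    return RGESRecord(profile.profile_id, es_up, es_down, es_up - es_down,
                      len(up), len(down))


def batch_score(matrix: ProfileMatrix, signature: DiseaseSignature,
                quality_only: bool = True,
                min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Score every (retained) profile in a matrix against a signature.

    With ``quality_only`` (default) profiles whose quality flag is false are
    dropped, mirroring the high-quality ("gold") filter applied to L1000
    signatures.  Output rows keep the input profile order and carry the
    condition metadata alongside the score components.
    """
    n_total = len(matrix)
    rows = []
    for profile in matrix:
        if quality_only and not profile.meta.quality_flag:
            continue
        rec = compute_rges(profile, signature, min_overlap=min_overlap)
        rows.append({
            "profile_id": rec.profile_id,
            "compound_id": profile.meta.compound_id,
            "cell_line": profile.meta.cell_line,
            "dose_um": profile.meta.dose_um,
            "time_h": profile.meta.time_h,
            "es_up": rec.es_up,
            "es_down": rec.es_down,
            "rges": rec.rges,
            "m_up": rec.m_up,
            "m_down": rec.m_down,
        })
    if not rows:
        raise DataError(
            f"no profiles left to score ({n_total} in matrix, all filtered out)"
        )
    if len(rows) < n_total:
        logger.info("batch_score: %d of %d profiles dropped by quality filter",
                    n_total - len(rows), n_total)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# alternative similarity scores and a permutation null
# ---------------------------------------------------------------------------

SimilarityMethod = Literal["spearman", "pearson", "cosine"]


def similarity_score(profile: DrugProfile, signature: DiseaseSignature,
                     method: SimilarityMethod = "spearman") -> float:
    """Correlation-type reversal score over the signature genes.

    Compares the profile's differential-expression values with the
    signature's log2 fold changes on the union of up and down genes; negative
    values indicate reversal.  Provided for benchmarking against the
    enrichment-based score.
    """
    genes = sorted(signature.genes & set(profile.values.index))
    if len(genes) < 3:
        raise DataError(f"only {len(genes)} signature genes present in profile "
                        f"(need >= 3)")
    x = profile.values[genes].to_numpy(dtype=float)
    y = np.array([signature.log2fc(g) for g in genes])
    if method in ("spearman", "pearson"):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DataError(f"zero-variance vector: {method} undefined")
        if method == "spearman":
            return float(sps.spearmanr(x, y).statistic)
        return float(sps.pearsonr(x, y).statistic)
    if method == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise DataError("zero-norm vector: cosine undefined")
        return float(np.dot(x, y) / (nx * ny))
    raise ValueError(f"unknown method {method!r}")


def _es_from_positions(v_sorted: np.ndarray, m: int, n: int) -> float:
    j = np.arange(1, m + 1, dtype=float)
    a = np.max(j / m - v_sorted / n)
    b = np.max(v_sorted / n - (j - 1) / m)
    return float(a) if a > b else float(-b)


def rges_pvalue(profile: DrugProfile, signature: DiseaseSignature,
                n_perm: int = 10000, seed: int = 0,
                min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Two-sided permutation P for one profile's RGES.

    The null redraws the up/down sets (sizes m_up, m_down, disjoint) uniformly
    from the universe and rescores; the P value is the add-one-smoothed
    fraction of permuted \\|RGES\\| at least as large as observed.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rec = compute_rges(profile, signature, min_overlap=min_overlap)
    ranked = rank_profile(profile)
    n = ranked.n
    m_up, m_down = rec.m_up, rec.m_down
    if m_up + m_down > n:
        raise DataError(f"signature larger than universe: {m_up}+{m_down} > {n}")
    positions = ranked.positions.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    observed = abs(rec.rges)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=m_up + m_down, replace=False)
        v_up = np.sort(positions[idx[:m_up]])
        v_down = np.sort(positions[idx[m_up:]])
        r = _es_from_positions(v_up, m_up, n) - _es_from_positions(v_down, m_down, n)
        if abs(r) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def save_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a per-profile score table as TSV."""
    scores.to_csv(path, sep="\t", index=False)


def load_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"profile_id": str, "compound_id": str, "cell_line": str}, float_precision="round_trip")
    missing = set(SCORE_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise DataError(f"score table {path} lacks column(s): {sorted(missing)}")
    return df
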