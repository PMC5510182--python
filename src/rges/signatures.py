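"""Disease gene-expression signatures.

A disease signature is the pair of gene sets significantly up- and
downregulated in diseased tissue relative to matched normal tissue,
restricted to the universe of directly measured ("landmark") genes of an
L1000-style platform.  Signatures are built from a differential-expression
table (gene, log2 fold change, adjusted P) by thresholding both statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Default absolute log2 fold-change threshold for signature membership.
DEFAULT_LFC_CUT = 1.5
#: Default adjusted-P threshold for signature membership.
DEFAULT_PADJ_CUT = 0.001
#: Below this many signature genes a disease is considered poorly powered
#: for reversal scoring; a warning (not an error) is emitted.
MIN_RECOMMENDED_DE_GENES = 50


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of the gene identifiers a platform measures directly.

    Order is preserved exactly as loaded so that downstream tie-breaking and
    serialization are deterministic.
    """

    genes: tuple[str, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError("gene universe is empty")
        index = {g: i for i, g in enumerate(self.genes)}
        if len(index) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise DataError(f"duplicate gene in universe: {dup!r}")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        return cls(tuple(str(g) for g in genes))


def load_universe(path: str | Path) -> GeneUniverse:
    """Read a universe file: one gene identifier per line, order kept."""
    lines = Path(path).read_text().splitlines()
    return GeneUniverse.from_iterable(g.strip() for g in lines if g.strip())


def save_universe(universe: GeneUniverse, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in universe.genes))


def load_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table.

    Tab-separated with header ``gene  log2fc  padj``.  Returns a DataFrame
    with those three columns; validation happens in :func:`build_signature`.
    """
    de = pd.read_csv(path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    missing = {"gene", "log2fc", "padj"} - set(de.columns)
    if missing:
        raise DataError(
            f"DE table {path} lacks required column(s): {', '.join(sorted(missing))}"
        )
    return de[["gene", "log2fc", "padj"]]


@dataclass(frozen=True)
class DiseaseSignature:
    """Up/down gene sets with per-gene statistics over a fixed universe.

    Invariants: ``up`` and ``down`` are disjoint subsets of the universe and
    their union is non-empty; every member passed both filter thresholds.
    """

    up: frozenset[str]
    down: frozenset[str]
    stats: Mapping[str, tuple[float, float]]  # gene -> (log2fc, padj)
    universe: GeneUniverse

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DataError("signature up and down sets overlap")
        if not (self.up or self.down):
            raise DataError("empty signature: no gene passed both thresholds")
        outside = (self.up | self.down) - set(self.universe.genes)
        if outside:
            raise DataError(f"signature genes outside universe: {sorted(outside)[:5]}")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def direction(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)

    def log2fc(self, gene: str) -> float:
        return self.stats[gene][0]

    def swapped(self) -> "DiseaseSignature":
        """Signature with the roles of up and down exchanged."""
        return DiseaseSignature(self.down, self.up, self.stats, self.universe)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.universe.genes:  # universe order -> deterministic output
            if gene in self.up or gene in self.down:
                lfc, padj = self.stats[gene]
                rows.append(
                    {
                        "gene": gene,
                        "direction": "up" if gene in self.up else "down",
                        "log2fc": lfc,
                        "padj": padj,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "direction", "log2fc", "padj"])

    def save(self, path: str | Path) -> None:
        """Write as TSV: ``gene  direction  log2fc  padj``; round-trips exactly."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_signature(path: str | Path, universe: GeneUniverse) -> DiseaseSignature:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str}, float_precision="round_trip")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise DataError(f"signature file {path}: invalid direction value(s) {bad}")
    up = frozenset(df.loc[df["direction"] == "up", "gene"])
    down = frozenset(df.loc[df["direction"] == "down", "gene"])
    stats = {r.gene: (float(r.log2fc), float(r.padj)) for r in df.itertuples()}
    return DiseaseSignature(up, down, stats, universe)


def build_signature(
    de: pd.DataFrame,
    universe: GeneUniverse,
    lfc_cut: float = DEFAULT_LFC_CUT,
    padj_cut: float = DEFAULT_PADJ_CUT,
) -> DiseaseSignature:
    """Threshold a DE table into a disease signature.

    A gene enters the up set when ``log2fc > lfc_cut`` and ``padj < padj_cut``
    (strict inequalities), the down set when ``log2fc < -lfc_cut`` and
    ``padj < padj_cut``.  The threshold applies to the magnitude of the fold
    change, split by sign, so one cut yields both directions.  Genes not in
    the universe are dropped (counted in the log); genes with a missing
    adjusted P are excluded, never imputed.

    Raises
    ------
    DataError
        If no gene passes both filters, or on malformed input.
    ValueError
        If ``lfc_cut`` or ``padj_cut`` violates its domain.
    """
    if de.empty:
        raise DataError("DE table is empty")
    if not lfc_cut > 0:
        raise ValueError(f"lfc_cut must be > 0, got {lfc_cut}")
    if not 0 < padj_cut <= 1:
        raise ValueError(f"padj_cut must be in (0, 1], got {padj_cut}")
    if de["gene"].duplicated().any():
        dup = de.loc[de["gene"].duplicated(), "gene"].iloc[0]
        raise DataError(f"DE table has more than one row for gene {dup!r}")

    n_missing_padj = int(de["padj"].isna().sum())
    de = de.dropna(subset=["padj"])
    if ((de["padj"] < 0) | (de["padj"] > 1)).any():
        raise DataError("adjusted P values outside [0, 1]")
    if not de["log2fc"].map(math.isfinite).all():
        raise DataError("non-finite log2 fold change in DE table")

    in_universe = de["gene"].isin(set(universe.genes))
    n_outside = int((~in_universe).sum())
    de = de[in_universe]

    passed = de[de["padj"] < padj_cut]
    up = frozenset(passed.loc[passed["log2fc"] > lfc_cut, "gene"])
    down = frozenset(passed.loc[passed["log2fc"] < -lfc_cut, "gene"])
    if not (up or down):
        raise DataError(
            f"empty signature: no gene passed |log2fc| > {lfc_cut} "
            f"and padj < {padj_cut}"
        )

    stats = {
        r.gene: (float(r.log2fc), float(r.padj))
        for r in de.itertuples()
        if r.gene in up or r.gene in down
    }
    logger.info(
        "signature: %d up, %d down (%d genes outside universe dropped, "
        "%d missing padj excluded)",
        len(up), len(down), n_outside, n_missing_padj,
    )
    if len(up) + len(down) <= MIN_RECOMMENDED_DE_GENES:
        logger.warning(
            "signature has only %d genes (<= %d); reversal scores for this "
            "disease may be poorly powered",
            len(up) + len(down), MIN_RECOMMENDED_DE_GENES,
        )
    return DiseaseSignature(up, down, stats, universe)
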