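"""Synthetic reversal studies with recorded ground truth.

Generates every input the pipeline consumes — landmark universe, disease
DE table/signature, drug-profile matrix with condition metadata, compound
efficacy (IC50) table, and cell-line/tumour expression matrices — from a
planted statistical model, so the whole package is testable without any
external download.

The model is parameterized in normalized rank positions, because every
downstream statistic is rank-based.  Each gene in a profile receives a
latent position t in (0, 1] (small t = top of the ranked list = most
upregulated); background genes draw t ~ Uniform(0, 1) while planted
reversal genes are shifted by the profile's effective reversal shift
sigma: disease-UP genes move down the list (t + sigma), disease-DOWN genes
move up (t - sigma).  With this uniform-plus-shift structure the realized
RGES is approximately -2*sigma (the KS maxima are b_up ~ sigma and
a_down ~ sigma), so a planted additive RGES *elevation* e for a
non-reference condition bin is realized by attenuating the shift by e/2.
The -2 slope holds in the working regime (|sigma| >~ 0.1); near the null
the enrichment maxima respond more steeply, so realized bin elevations in
a full study are faithful for strongly reversing compounds and somewhat
inflated for near-null ones.  :func:`simulate_condition_rges` plants
additive effects directly on the RGES scale and is the reference fixture
for validating offset estimation in isolation.

The effective shift of one profile is

    sigma = strength(compound) * rho(cell line) - elevation(bin)/2 + noise

i.e. reversal measured in a cell line transcriptionally distant from the
tumours (small rho) is attenuated — the premise behind correlation
weighting — and lower dose / shorter treatment weakens reversal, the
premise behind condition normalization.  IC50s follow a lognormal link
ic50 = exp(a - b*strength + eps), decreasing in true reversal strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ProfileMatrix, SCORE_COLUMNS
from .errors import DataError
from .signatures import DiseaseSignature, GeneUniverse, build_signature, save_universe
from .srges import ALL_BINS, REFERENCE_BIN, ConditionBin

#: Slope of realized RGES per unit of planted rank shift under the
#: uniform-plus-shift position model (derived analytically, verified by
#: simulation); used to convert a planted RGES elevation into a shift
#: attenuation.
RGES_PER_SHIFT = -2.0

_DEFAULT_OFFSETS = {
    ConditionBin("low", "long"): 0.10,
    ConditionBin("high", "short"): 0.15,
    ConditionBin("low", "short"): 0.20,
}
_DEFAULT_RHO = {"CELL_A": 0.9, "CELL_B": 0.6, "CELL_C": 0.3}
_BIN_CONDITIONS = {
    ConditionBin("high", "long"): (10.0, 24.0),
    ConditionBin("high", "short"): (10.0, 6.0),
    ConditionBin("low", "long"): (5.0, 24.0),
    ConditionBin("low", "short"): (5.0, 6.0),
}


@dataclass
class SimConfig:
    """Parameters of a synthetic reversal study.

    ``reversal_strength`` is the mean rank shift (in normalized-position
    units) that an effective compound imposes on the planted reversal genes
    at the reference condition in a perfectly tumour-like cell line.
    ``condition_offsets`` are the planted RGES elevations of the
    non-reference bins (positive = weaker reversal there).  ``ic50_a``,
    ``ic50_b`` and ``ic50_noise_sd`` parameterize the lognormal efficacy
    link ic50 = exp(a - b*strength + eps); the defaults place a strength-0.3
    compound near 1.8 uM and a strength-0 compound near 20 uM, so the 10 uM
    activity threshold splits the groups non-trivially.
    """

    n_genes: int = 978
    n_up: int = 50
    n_down: int = 50
    n_reversal_up: int | None = None      # default: all up signature genes
    n_reversal_down: int | None = None    # default: all down signature genes
    n_effective: int = 30
    n_ineffective: int = 30
    reversal_strength: float = 0.3
    condition_offsets: dict[ConditionBin, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS))
    noise_sd: float = 0.05
    cell_tumour_rho: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RHO))
    n_tumours: int = 20
    ic50_a: float = 3.0
    ic50_b: float = 8.0
    ic50_noise_sd: float = 0.5
    p_cell: float = 0.7            # chance a compound is profiled in a cell line
    n_target_profiles: int = 2     # target-bin profiles per (compound, cell)
    low_quality_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reversal_up is None:
            self.n_reversal_up = self.n_up
        if self.n_reversal_down is None:
            self.n_reversal_down = self.n_down
        for name in ("n_genes", "n_up", "n_down", "n_effective", "n_ineffective",
                     "n_tumours"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.n_up + self.n_down >= self.n_genes:
            raise DataError("signature cannot cover the whole universe")
        if self.n_reversal_up > self.n_up or self.n_reversal_down > self.n_down:
            raise DataError("more planted reversal genes than signature genes")
        if self.reversal_strength < 0:
            raise DataError("reversal_strength must be >= 0")
        max_shift = (self.reversal_strength * 1.5
                     + 3 * self.noise_sd)
        if max_shift >= 1.0:
            raise DataError(
                f"infeasible config: planted shift up to {max_shift:.2f} pushes "
                f"normalized positions outside (0, 1]"
            )
        for cell, rho in self.cell_tumour_rho.items():
            if not 0 <= rho <= 1:
                raise DataError(f"rho for {cell} outside [0, 1]: {rho}")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated study."""

    reversal_up: list[str]
    reversal_down: list[str]
    strength: dict[str, float]                 # compound -> true reversal strength
    elevations: dict[str, float]               # "dose_class/time_class" -> planted RGES elevation
    rho: dict[str, float]                      # cell line -> planted tumour similarity
    effective_compounds: list[str]
    ineffective_compounds: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class SimStudy:
    """A complete simulated study: all pipeline inputs plus the truth."""

    universe: GeneUniverse
    de_table: pd.DataFrame
    signature: DiseaseSignature
    matrix: ProfileMatrix
    efficacy: pd.DataFrame
    cell_expr: pd.DataFrame
    tumour_expr: pd.DataFrame
    truth: SimTruth

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_universe(self.universe, outdir / "universe.txt")
        self.de_table.to_csv(outdir / "de.tsv", sep="\t", index=False)
        self.signature.save(outdir / "signature.tsv")
        self.matrix.save(outdir / "profiles.tsv", outdir / "profile_meta.tsv")
        self.efficacy.to_csv(outdir / "efficacy.tsv", sep="\t", index=False)
        self.cell_expr.to_csv(outdir / "cell_expr.tsv", sep="\t",
                              index_label="gene")
        self.tumour_expr.to_csv(outdir / "tumour_expr.tsv", sep="\t",
                                index_label="gene")
        self.truth.save(outdir / "truth.json")


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _make_de_table(rng: np.random.Generator, universe: GeneUniverse,
                   up: list[str], down: list[str]) -> pd.DataFrame:
    """DE table whose default-threshold signature is exactly (up, down)."""
    up_set, down_set = set(up), set(down)
    rows = []
    for g in universe.genes:
        if g in up_set:
            lfc = rng.uniform(2.0, 4.0)
            padj = 10 ** rng.uniform(-9, -6)
        elif g in down_set:
            lfc = -rng.uniform(2.0, 4.0)
            padj = 10 ** rng.uniform(-9, -6)
        else:
            lfc = rng.normal(0.0, 0.4)
            padj = rng.uniform(0.3, 1.0)
        rows.append({"gene": g, "log2fc": lfc, "padj": padj})
    return pd.DataFrame(rows)


def simulate_cell_expression(n_genes: int, rho_per_cell: dict[str, float],
                             n_tumours: int, seed: int,
                             tumour_noise_sd: float = 0.5,
                             cell_noise_sd: float | None = None,
                             gene_names: list[str] | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-line and tumour expression under a shared-factor mixture.

    A latent tumour factor F ~ N(0,1) per gene drives both matrices: tumour
    t = F + tumour_noise_sd * eta_t; cell line c = rho_c * F +
    sqrt(1 - rho_c^2) * eps_c (unit marginal variance).  The expected rank
    correlation between a cell line and the tumours increases monotonically
    with rho and is *proportional* to rho, so max-normalized weights recover
    rho ratios.  ``cell_noise_sd`` overrides the unit-variance noise scale
    (0 gives the deterministic rho=1 limit).
    """
    for cell, rho in rho_per_cell.items():
        if not 0 <= rho <= 1:
            raise DataError(f"rho for {cell} outside [0, 1]: {rho}")
    rng = np.random.default_rng(seed)
    genes = gene_names if gene_names is not None else [
        f"G{i + 1:04d}" for i in range(n_genes)]
    factor = rng.normal(size=n_genes)
    tumours = factor[:, None] + tumour_noise_sd * rng.normal(size=(n_genes, n_tumours))
    tumour_expr = pd.DataFrame(
        tumours, index=genes,
        columns=[f"T{j + 1:03d}" for j in range(n_tumours)])
    cols = {}
    for cell in sorted(rho_per_cell):
        rho = rho_per_cell[cell]
        noise_scale = (np.sqrt(1 - rho ** 2) if cell_noise_sd is None
                       else cell_noise_sd)
        cols[cell] = rho * factor + noise_scale * rng.normal(size=n_genes)
    cell_expr = pd.DataFrame(cols, index=genes)
    return cell_expr, tumour_expr


def _profile_values(rng: np.random.Generator, n_genes: int,
                    up_idx: np.ndarray, down_idx: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Differential-expression values realizing the planted rank shifts."""
    t = rng.uniform(size=n_genes)
    t[up_idx] = t[up_idx] + sigma      # toward the bottom of the list
    t[down_idx] = t[down_idx] - sigma  # toward the top
    np.clip(t, 1e-6, 1.0 - 1e-6, out=t)
    # any strictly decreasing map of t yields the same ranks; a normal
    # quantile keeps the values looking like z-scored differential expression
    return sps.norm.ppf(1.0 - t)


def simulate_study(cfg: SimConfig | None = None) -> SimStudy:
    """Generate a complete study from a :class:`SimConfig`.

    Fully reproducible: the same config (including seed) yields
    byte-identical serialized output.
    """
    cfg = cfg if cfg is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    universe = GeneUniverse.from_iterable(genes)
    sig_idx = rng.choice(cfg.n_genes, size=cfg.n_up + cfg.n_down, replace=False)
    up_genes = sorted(genes[i] for i in sig_idx[:cfg.n_up])
    down_genes = sorted(genes[i] for i in sig_idx[cfg.n_up:])
    reversal_up = up_genes[:cfg.n_reversal_up]
    reversal_down = down_genes[:cfg.n_reversal_down]
    up_idx = np.array([universe.index_of(g) for g in reversal_up], dtype=int)
    down_idx = np.array([universe.index_of(g) for g in reversal_down], dtype=int)

    de_table = _make_de_table(rng, universe, up_genes, down_genes)
    signature = build_signature(de_table, universe)
    assert signature.up == frozenset(up_genes) and signature.down == frozenset(down_genes)

    # --- compounds and true strengths ------------------------------------
    compounds = [f"CPD{k + 1:04d}" for k in range(cfg.n_effective + cfg.n_ineffective)]
    effective = compounds[:cfg.n_effective]
    ineffective = compounds[cfg.n_effective:]
    strength: dict[str, float] = {}
    for c in effective:
        strength[c] = float(cfg.reversal_strength * rng.uniform(0.5, 1.5))
    for c in ineffective:
        strength[c] = float(cfg.reversal_strength * rng.uniform(0.0, 0.15))

    cells = sorted(cfg.cell_tumour_rho)
    target_bins = [b for b in ALL_BINS if b != REFERENCE_BIN]
    elevations = {b: float(cfg.condition_offsets.get(b, 0.0)) for b in target_bins}

    # --- profiles ---------------------------------------------------------
    values_cols: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    pid = 0
    for compound in compounds:
        tested = [c for c in cells if rng.uniform() < cfg.p_cell]
        if not tested:
            tested = [cells[int(rng.integers(len(cells)))]]
        for cell in tested:
            rho = cfg.cell_tumour_rho[cell]
            bins = [REFERENCE_BIN] + [
                target_bins[int(rng.integers(len(target_bins)))]
                for _ in range(cfg.n_target_profiles)
            ]
            for b in bins:
                elev = 0.0 if b == REFERENCE_BIN else elevations[b]
                sigma = (strength[compound] * rho
                         + elev / RGES_PER_SHIFT          # i.e. minus elev/2
                         + rng.normal(0.0, cfg.noise_sd))
                pid += 1
                profile_id = f"P{pid:05d}"
                values_cols[profile_id] = _profile_values(
                    rng, cfg.n_genes, up_idx, down_idx, sigma)
                dose, time = _BIN_CONDITIONS[b]
                meta_rows[profile_id] = {
                    "compound_id": compound,
                    "cell_line": cell,
                    "dose_um": dose,
                    "time_h": time,
                    "quality_flag": bool(rng.uniform() >= cfg.low_quality_frac),
                }
    values = pd.DataFrame(values_cols, index=genes)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "profile_id"
    matrix = ProfileMatrix(universe, values, meta)

    # --- efficacy ---------------------------------------------------------
    eff_rows = []
    for compound in compounds:
        for _ in range(int(rng.integers(1, 4))):  # 1-3 IC50 measurements
            ic50 = float(np.exp(cfg.ic50_a - cfg.ic50_b * strength[compound]
                                + rng.normal(0.0, cfg.ic50_noise_sd)))
            eff_rows.append({
                "compound_id": compound,
                "cell_line": cells[int(rng.integers(len(cells)))],
                "ic50_um": ic50,
            })
    efficacy = pd.DataFrame(eff_rows)

    # --- cell/tumour expression ------------------------------------------
    cell_expr, tumour_expr = simulate_cell_expression(
        cfg.n_genes, cfg.cell_tumour_rho, cfg.n_tumours,
        seed=int(rng.integers(2 ** 31)), gene_names=genes)

    truth = SimTruth(
        reversal_up=reversal_up,
        reversal_down=reversal_down,
        strength=strength,
        elevations={f"{b.dose_class}/{b.time_class}": e
                    for b, e in elevations.items()},
        rho={c: float(cfg.cell_tumour_rho[c]) for c in cells},
        effective_compounds=effective,
        ineffective_compounds=ineffective,
    )
    return SimStudy(universe, de_table, signature, matrix, efficacy,
                    cell_expr, tumour_expr, truth)


def simulate_condition_rges(elevations: dict[ConditionBin, float] | None = None,
                            noise_sd: float = 0.05, n_pairs: int = 300,
                            seed: int = 0, base_mean: float = -0.3,
                            base_sd: float = 0.2) -> pd.DataFrame:
    """Per-profile score table with planted additive condition effects.

    For each of ``n_pairs`` (compound, cell line) pairs a latent baseline
    RGES is drawn; the pair gets one reference-condition profile at that
    baseline and one profile per target bin elevated by the planted amount,
    all perturbed by N(0, noise_sd).  Used to validate offset estimation in
    isolation: ``estimate_offsets`` should recover -elevation per bin.
    """
    elevations = dict(_DEFAULT_OFFSETS) if elevations is None else elevations
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for k in range(n_pairs):
        base = rng.normal(base_mean, base_sd)
        for b in [REFERENCE_BIN] + sorted(elevations):
            elev = 0.0 if b == REFERENCE_BIN else elevations[b]
            dose, time = _BIN_CONDITIONS[b]
            pid += 1
            rows.append({
                "profile_id": f"P{pid:05d}",
                "compound_id": f"CPD{k + 1:04d}",
                "cell_line": "CELL_A",
                "dose_um": dose,
                "time_h": time,
                "es_up": np.nan,
                "es_down": np.nan,
                "rges": float(base + elev + rng.normal(0.0, noise_sd)),
                "m_up": 0,
                "m_down": 0,
            })
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
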