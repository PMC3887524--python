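"""Synthetic two-color spotted-array data with known planted truth.

The generator emulates a direct dye-swap comparison between two genotypes
that differ only in sex-chromosome parent-of-origin: eight replicate arrays
(dye-swapped), ~21,500 spots per array, an intensity-dependent dye bias, a
smooth spatial artifact over the slide, a configurable fraction of
QC-failing spots, and planted per-gene log2 effects in which testis-specific
genes are shifted as a group in one direction and adult-midgut-specific
genes in the other.  A matching tissue-expression atlas is generated so
that designated tissue-specific genes are recovered by the τ classifier.

Noise model
-----------
Per-spot channel medians are produced in closed form from the planted
log2 ratio M and a per-gene baseline intensity A:

    fg_ch1 = 2**(A + M/2),   fg_ch2 = 2**(A - M/2)

with M = orientation * effect + dye_bias(A) + spatial(x, y) + technical
noise.  Pixel-level populations are never simulated; the summary columns
that the QC criteria reference (pixel counts, fraction of foreground pixels
above background + 2 SD, background medians/SDs) are drawn directly, and
QC-failing spots are constructed to violate one criterion explicitly, so
every spot carries an exact planted pass/fail flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ARMS, CHROMATIN_COLORS, SPOT_COLUMNS, Hybridization
from .tissue_specificity import TISSUES, TissueAtlas

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_gene_catalog",
    "generate_planted_truth",
    "generate_tissue_atlas",
    "generate_hybridizations",
    "simulate_experiment",
]

# Spot counts per chromosome arm on the printed array (X, 2L, 2R, 3L, 3R, 4,
# unmapped), used as default catalog proportions.  The unmapped fraction is
# carried as its own category; mapped-only shares (e.g. 16.8% X-linked)
# follow from these counts.
_ARM_COUNTS = {
    "X": 2719, "2L": 2992, "2R": 3225, "3L": 3235, "3R": 3915,
    "4": 98, "Other": 514,
}
_ARM_TOTAL = sum(_ARM_COUNTS.values())  # 16,698
DEFAULT_ARM_PROPORTIONS = {k: v / _ARM_TOTAL for k, v in _ARM_COUNTS.items()}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic parent-of-origin contrast.

    Shift parameters are in log2 units.  ``biological_sd`` is the spread of
    per-gene true effects around their class median; ``technical_sd`` is the
    per-spot measurement noise.  Defaults describe a well-replicated
    whole-male contrast: 8 dye-swapped arrays, a full-size array, 12%
    testis-specific and 0.8% adult-midgut-specific genes, group median
    shifts of +0.24 (testis), -0.23 (midgut) and -0.03 (all other genes).
    """

    n_genes: int = 21487
    chromosome_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_ARM_PROPORTIONS))
    prop_testis_specific: float = 0.12
    prop_midgut_specific: float = 0.008
    n_arrays: int = 8
    dye_swap_pattern: tuple | None = None  # default: alternate +1/-1
    testis_median_shift: float = 0.24
    midgut_median_shift: float = -0.23
    background_shift: float = -0.03
    biological_sd: float = 0.12
    technical_sd: float = 0.07
    dye_bias_amplitude: float = 0.30
    spatial_amplitude: float = 0.15
    qc_fail_fraction: float = 0.05
    grid_shape: tuple = (147, 147)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        tot = sum(self.chromosome_proportions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"chromosome_proportions sum to {tot}, not 1")
        unknown = set(self.chromosome_proportions) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms in proportions: {sorted(unknown)}")
        for name in ("prop_testis_specific", "prop_midgut_specific",
                     "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.prop_testis_specific + self.prop_midgut_specific > 1.0:
            raise ValueError("tissue-class proportions exceed 1")
        rows, cols = self.grid_shape
        if rows * cols < self.n_genes:
            raise ValueError(
                f"grid capacity {rows * cols} < n_genes {self.n_genes}")
        if self.n_arrays < 1:
            raise ValueError("n_arrays must be >= 1")
        if self.dye_swap_pattern is not None:
            if len(self.dye_swap_pattern) != self.n_arrays:
                raise ValueError("dye_swap_pattern length != n_arrays")
            if any(o not in (+1, -1) for o in self.dye_swap_pattern):
                raise ValueError("dye_swap_pattern entries must be +1/-1")
        for name in ("biological_sd", "technical_sd", "dye_bias_amplitude",
                     "spatial_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def orientations(self) -> np.ndarray:
        if self.dye_swap_pattern is not None:
            return np.asarray(self.dye_swap_pattern, dtype=int)
        return np.array([1 if j % 2 == 0 else -1
                         for j in range(self.n_arrays)], dtype=int)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.dye_swap_pattern is not None:
            d["dye_swap_pattern"] = list(self.dye_swap_pattern)
        return d


@dataclass
class PlantedTruth:
    """Ground truth recorded for recovery tests.

    ``effects`` is the per-gene true log2 fold-change (genotype A over
    genotype B); ``qc_fail`` is a genes x arrays boolean frame marking spots
    constructed to violate at least one QC criterion.
    """

    effects: pd.Series
    tissue_class: pd.Series
    qc_fail: pd.DataFrame
    orientations: np.ndarray


def _largest_remainder(n: int, proportions: dict, order: tuple) -> dict:
    """Integer counts summing to n; ties in remainders broken by ``order``."""
    keys = [k for k in order if k in proportions]
    quotas = np.array([n * proportions[k] for k in keys])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # stable sort: descending remainder, ties by listed order
    remainders = quotas - counts
    pick = np.argsort(-remainders, kind="stable")[:short]
    counts[pick] += 1
    return dict(zip(keys, counts))


def generate_gene_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Gene catalog: gene_id, chromosome arm, chromatin color, tissue class.

    Arm counts follow ``chromosome_proportions`` under largest-remainder
    rounding; tissue classes (testis / midgut / none) likewise.  Chromatin
    colors are assigned uniformly at random as plain labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_genes
    gene_ids = [f"g{i:06d}" for i in range(1, n + 1)]

    arm_counts = _largest_remainder(n, config.chromosome_proportions, ARMS)
    arms = np.repeat([k for k in ARMS if k in arm_counts],
                     [arm_counts[k] for k in ARMS if k in arm_counts])
    arms = arms[rng.permutation(n)]

    class_counts = _largest_remainder(
        n,
        {"testis": config.prop_testis_specific,
         "midgut": config.prop_midgut_specific,
         "none": 1.0 - config.prop_testis_specific - config.prop_midgut_specific},
        ("testis", "midgut", "none"),
    )
    classes = np.repeat(list(class_counts), list(class_counts.values()))
    classes = classes[rng.permutation(n)]

    colors = rng.choice(CHROMATIN_COLORS, size=n)
    return pd.DataFrame({
        "gene_id": gene_ids,
        "arm": arms,
        "chromatin_color": colors,
        "tissue_class": classes,
    })


def generate_planted_truth(catalog: pd.DataFrame,
                           config: SimulationConfig) -> PlantedTruth:
    """Draw per-gene true effects and per-spot QC-fail flags.

    Class effects are drawn around the configured shift and then recentered
    so the class median equals the shift exactly; unaffected genes are
    centered on ``background_shift`` the same way.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(catalog)
    eff = np.empty(n)
    cls = catalog["tissue_class"].to_numpy()
    for name, shift in (("testis", config.testis_median_shift),
                        ("midgut", config.midgut_median_shift),
                        ("none", config.background_shift)):
        mask = cls == name
        if mask.sum() == 0:
            continue
        draw = rng.normal(shift, config.biological_sd, mask.sum())
        eff[mask] = draw - np.median(draw) + shift

    fail = rng.random((n, config.n_arrays)) < config.qc_fail_fraction
    return PlantedTruth(
        effects=pd.Series(eff, index=catalog["gene_id"].to_numpy(), name="effect"),
        tissue_class=pd.Series(cls, index=catalog["gene_id"].to_numpy(),
                               name="tissue_class"),
        qc_fail=pd.DataFrame(fail, index=catalog["gene_id"].to_numpy(),
                             columns=[f"array{j + 1:02d}"
                                      for j in range(config.n_arrays)]),
        orientations=config.orientations,
    )


def generate_tissue_atlas(catalog: pd.DataFrame,
                          config: SimulationConfig,
                          absent_fraction: float = 0.10,
                          multi_probe_fraction: float = 0.10) -> TissueAtlas:
    """Tissue atlas with presence calls matching the planted tissue classes.

    Designated tissue-specific genes get a strong signal in their target
    tissue and mostly-absent calls elsewhere (a small leak probability keeps
    profiles realistic without dropping τ below the 0.9 cutoff).  A fraction
    of genes carries a second, weaker probe set to exercise probe-set
    collapsing.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_t = len(TISSUES)
    target = {"testis": "testes", "midgut": "adult midgut"}

    rows, probe_ids, gene_ids, calls = [], [], [], []

    def add_probe(gene, values, present, k):
        probe_ids.append(f"{gene}_ps{k}")
        gene_ids.append(gene)
        rows.append(values)
        calls.append(present)

    for gene, cls in zip(catalog["gene_id"], catalog["tissue_class"]):
        n_probes = 2 if rng.random() < multi_probe_fraction else 1
        for k in range(1, n_probes + 1):
            scale = 1.0 if k == 1 else 0.3  # redundant probe set is weaker
            if cls in target:
                values = rng.uniform(20.0, 180.0, n_t)
                present = rng.random(n_t) < 0.05  # rare low-level leak
                values = np.where(present, 2.0 ** rng.uniform(1.0, 2.5, n_t),
                                  values)
                ti = TISSUES.index(target[cls])
                values[ti] = 2.0 ** rng.normal(10.0, 0.5)
                present[ti] = True
            else:
                base = rng.normal(6.0, 1.0)
                values = 2.0 ** rng.normal(base, 0.8, n_t)
                present = rng.random(n_t) >= absent_fraction
            add_probe(gene, values * scale, present, k)

    values = pd.DataFrame(rows, index=probe_ids, columns=list(TISSUES))
    present = pd.DataFrame(calls, index=probe_ids, columns=list(TISSUES))
    genes = pd.Series(gene_ids, index=probe_ids, name="gene_id")
    return TissueAtlas(values=values, present=present, genes=genes)


def _dye_bias(A: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth cubic intensity-dependent dye bias, scaled to +-amplitude."""
    if amplitude == 0.0:
        return np.zeros_like(A)
    z = (A - 10.0) / 2.0
    f = 0.5 * z ** 3 - 0.75 * z
    m = np.max(np.abs(f))
    return amplitude * f / m if m > 0 else np.zeros_like(A)


def _spatial_field(u: np.ndarray, v: np.ndarray, amplitude: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Low-order polynomial + one Gaussian bump over unit-square coords."""
    a1, a2, a3 = rng.uniform(-1.0, 1.0, 3)
    u0, v0 = rng.uniform(0.2, 0.8, 2)
    b = rng.uniform(0.5, 1.5)
    f = a1 * u + a2 * v + a3 * u * v + b * np.exp(
        -((u - u0) ** 2 + (v - v0) ** 2) / (2 * 0.2 ** 2))
    if amplitude == 0.0:
        return np.zeros_like(f)
    f = f - f.mean()
    m = np.max(np.abs(f))
    return amplitude * f / m if m > 0 else np.zeros_like(f)


#: grid pitch in micrometers between adjacent spots
_SPOT_PITCH_UM = 150.0


def generate_hybridizations(catalog: pd.DataFrame, truth: PlantedTruth,
                            config: SimulationConfig) -> list[Hybridization]:
    """Simulate the spot tables of every array in the contrast.

    Each array places one spot per gene on the grid in row-major order.
    Arrays are split into two equal batches (independent labelings in the
    real experiment); the dye orientation follows ``config.orientations``.
    """
    if not truth.effects.index.equals(pd.Index(catalog["gene_id"]))\
            and list(truth.effects.index) != list(catalog["gene_id"]):
        raise ValueError("truth is not consistent with catalog")
    n = len(catalog)
    rows, cols = config.grid_shape
    rng_base = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    # per-gene baseline log2 intensity: property of the probe, shared by arrays
    A0 = np.clip(rng_base.normal(10.0, 1.2, n), 6.5, 13.5)

    grid_row = np.arange(n) // cols + 1
    grid_col = np.arange(n) % cols + 1
    x = grid_col.astype(float) * _SPOT_PITCH_UM
    y = grid_row.astype(float) * _SPOT_PITCH_UM
    u = (grid_col - 1) / max(cols - 1, 1)
    v = (grid_row - 1) / max(rows - 1, 1)

    effects = truth.effects.to_numpy()
    orientations = config.orientations
    hybs: list[Hybridization] = []
    for j in range(config.n_arrays):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4, j]))
        o = int(orientations[j])
        M = (o * effects
             + _dye_bias(A0, config.dye_bias_amplitude)
             + _spatial_field(u, v, config.spatial_amplitude, rng)
             + (rng.normal(0.0, config.technical_sd, n)
                if config.technical_sd > 0 else 0.0))
        fg1 = 2.0 ** (A0 + M / 2.0)
        fg2 = 2.0 ** (A0 - M / 2.0)

        # nominal passing QC summaries
        bg1 = fg1 / 10.0
        bg2 = fg2 / 10.0
        frac1 = rng.uniform(0.75, 1.0, n)
        frac2 = rng.uniform(0.75, 1.0, n)
        px1 = rng.integers(45, 90, n)
        px2 = rng.integers(45, 90, n)

        fail = truth.qc_fail.iloc[:, j].to_numpy()
        mode = rng.integers(1, 4, n)  # which criterion to violate
        m1 = fail & (mode == 1)
        frac1[m1] = rng.uniform(0.0, 0.695, m1.sum())
        frac2[m1] = rng.uniform(0.0, 0.695, m1.sum())
        m2 = fail & (mode == 2)
        bg1[m2] = fg1[m2] / 2.0  # fg/bg ratio 2 < 3 in both channels
        bg2[m2] = fg2[m2] / 2.0
        m3 = fail & (mode == 3)
        px1[m3] = rng.integers(5, 31, m3.sum())  # <= 30 foreground pixels

        spots = pd.DataFrame({
            "probe_id": catalog["gene_id"].to_numpy(),
            "block": np.ones(n, dtype=int),
            "row": grid_row,
            "col": grid_col,
            "x": x,
            "y": y,
            "fg_median_ch1": fg1,
            "fg_pixels_ch1": px1,
            "frac_fg_gt_bg2sd_ch1": frac1,
            "bg_median_ch1": bg1,
            "bg_sd_ch1": bg1 / 4.0,
            "fg_median_ch2": fg2,
            "fg_pixels_ch2": px2,
            "frac_fg_gt_bg2sd_ch2": frac2,
            "bg_median_ch2": bg2,
            "bg_sd_ch2": bg2 / 4.0,
        }, columns=SPOT_COLUMNS)
        hybs.append(Hybridization(
            array_id=f"array{j + 1:02d}",
            batch=f"batch{j // max(config.n_arrays // 2, 1) + 1}",
            orientation=o,
            spots=spots,
        ))
    return hybs


def simulate_experiment(config: SimulationConfig):
    """Convenience: catalog, truth, atlas and hybridizations in one call."""
    catalog = generate_gene_catalog(config)
    truth = generate_planted_truth(catalog, config)
    atlas = generate_tissue_atlas(catalog, config)
    hybs = generate_hybridizations(catalog, truth, config)
    return catalog, truth, atlas, hybs
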