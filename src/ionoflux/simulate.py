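"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: tidy ionome
tables over the destructive-harvest design (5 replicates x {control, WD} x
4 water-deficit harvests plus the shared pre-treatment harvest t0),
phenotype tables, NB-distributed RNA-seq count matrices with planted
differentially expressed genes, gene-element annotation tables, and RGB
plant images with known areas.

Design of the ionome generator
------------------------------
The planted ground truth is the *relative net uptake* per element and WD
harvest: the uptake multiplier m acts on the plant-total net uptake,

    Q_WD(t') = Q(t0) + m * (Q_control(t') - Q(t0)),

and the implied concentration scaling is spread uniformly over tissues.
With zero noise the downstream relative NU therefore equals m exactly, and
the WD/control concentration ratio equals the closed-form factor
f = (Q0 + m*(Qc - Q0)) / Qc.

Noise is multiplicative lognormal with unit mean on concentrations and dry
weights: measured concentrations are positive and their coefficient of
variation is constant, which matches how ICP-MS replicate scatter is
usually summarized even though the instrument's true error law is not
published. ``noise_cv = 0`` reproduces the closed-form truth exactly.

All generators are pure functions of (config, seed); the one integer seed
is split deterministically per generator via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ionome import ELEMENTS, HARVESTS, TISSUES_3, TISSUES_5, WD_HARVESTS
from .phenotyping import ImageRecord

# stream indices for deterministic per-generator seed splitting
_STREAM = {"ionome": 0, "counts": 1, "annotation": 2, "image": 3, "phenotype": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(max(_STREAM.values()) + 1)
    return np.random.default_rng(child[_STREAM[stream]])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# ionome + phenotype generator
# ---------------------------------------------------------------------------

#: Typical tissue concentrations (ppm of dry weight) used as defaults;
#: macronutrients in the 1e3-1e4 range, micronutrients 1-100, trace < 1.
_DEFAULT_PPM = {
    "N": 30000.0, "Mg": 2000.0, "P": 4000.0, "S": 5000.0, "K": 25000.0,
    "Ca": 15000.0, "B": 30.0, "Cl": 5000.0, "Mn": 50.0, "Fe": 100.0,
    "Ni": 1.0, "Cu": 5.0, "Zn": 40.0, "Mo": 1.0, "Na": 500.0, "Co": 0.2,
    "V": 0.1, "Se": 0.1, "Si": 300.0, "Al": 30.0,
}

#: Per-tissue dry-weight trajectory (g) over the harvests. The growth
#: multipliers follow the vegetative (near-exponential) growth of young
#: rapeseed/wheat: roughly 1.8x five days after t0, ~10x after three weeks,
#: consistent with published control biomass trajectories for these stages.
_DW_BASE = {"roots": 0.3, "OLB": 1.7, "OP": 0.8, "YLB": 0.6, "YP": 0.3}
_DW_GROWTH = {"t0": 1.0, "t1_40": 1.8, "t1_25": 4.6, "t2_40": 8.3, "t2_25": 10.4}

#: Phenotype control baselines (rapeseed-like) and WD fold changes by harvest.
_PHENO_BASE = {"A": 15.0, "E": 4.0, "gs": 0.34, "ABA": 38.0, "SA": 85.0,
               "delta13C": -32.0}
_PHENO_WD_EFFECT = {
    "A": {"t1_40": 0.9, "t1_25": 0.3, "t2_40": 0.55, "t2_25": 0.2},
    "E": {"t1_40": 0.65, "t1_25": 0.12, "t2_40": 0.65, "t2_25": 0.1},
    "gs": {"t1_40": 0.6, "t1_25": 0.1, "t2_40": 0.7, "t2_25": 0.1},
    "ABA": {"t1_40": 1.8, "t1_25": 4.4, "t2_40": 2.6, "t2_25": 6.3},
    "SA": {"t1_40": 1.2, "t1_25": 5.0, "t2_40": 0.1, "t2_25": 0.11},
    "delta13C": {"t1_40": 0.995, "t1_25": 0.94, "t2_40": 0.995, "t2_25": 0.93},
}


@dataclass
class IonomeSimConfig:
    """Configuration of the synthetic destructive-harvest ionome study."""

    species: str = "rapeseed"
    tissues: Sequence[str] = ()
    elements: Sequence[str] = ELEMENTS
    harvests: Sequence[str] = HARVESTS
    n_replicates: int = 5
    baseline_concentration: Optional[pd.DataFrame] = None  # element x tissue, ppm
    baseline_dry_weight: Optional[pd.DataFrame] = None     # tissue x harvest, g
    uptake_multiplier: Optional[pd.DataFrame] = None       # element x WD harvest
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            self.tissues = TISSUES_5 if self.species == "rapeseed" else TISSUES_3
        self.tissues = tuple(self.tissues)
        self.elements = tuple(self.elements)
        if len(self.elements) != len(set(self.elements)):
            raise ValueError("element list has duplicates")
        if len(self.elements) != 20:
            raise ValueError(
                f"the functional ionome has exactly 20 elements, got {len(self.elements)}"
            )
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.baseline_concentration is None:
            self.baseline_concentration = pd.DataFrame(
                {t: [_DEFAULT_PPM[e] for e in self.elements] for t in self.tissues},
                index=list(self.elements),
            )
        if self.baseline_dry_weight is None:
            self.baseline_dry_weight = pd.DataFrame(
                {h: [_DW_BASE[t] * _DW_GROWTH[h] for t in self.tissues]
                 for h in self.harvests},
                index=list(self.tissues),
            )
        if self.uptake_multiplier is None:
            self.uptake_multiplier = pd.DataFrame(
                1.0, index=list(self.elements),
                columns=[h for h in self.harvests if h != "t0"],
            )
        if (self.baseline_concentration.to_numpy() <= 0).any():
            raise ValueError("all baseline concentrations must be > 0 ppm")
        if (self.baseline_dry_weight.to_numpy() <= 0).any():
            raise ValueError("all baseline dry weights must be > 0 g")
        if (self.uptake_multiplier.to_numpy() < 0).any():
            raise ValueError("uptake multipliers must be >= 0")


@dataclass
class IonomeTruth:
    """Closed-form ground truth of the generator at zero noise."""

    relative_nu: pd.DataFrame            # element x WD harvest (= multiplier)
    concentration_ratio: pd.DataFrame    # element x WD harvest (factor f)


def _wd_concentration_factor(config: IonomeSimConfig) -> pd.DataFrame:
    """Per element x WD harvest factor f scaling control concentrations."""
    conc = config.baseline_concentration  # element x tissue
    dw = config.baseline_dry_weight       # tissue x harvest
    q0 = conc.mul(dw["t0"], axis=1).sum(axis=1)  # per element
    out = {}
    for h in config.uptake_multiplier.columns:
        qc = conc.mul(dw[h], axis=1).sum(axis=1)
        m = config.uptake_multiplier[h]
        out[h] = (q0 + m * (qc - q0)) / qc
    return pd.DataFrame(out)


def gen_ionome_dataset(
    config: IonomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, IonomeTruth]:
    """Generate a tidy ionome table, phenotype table and the planted truth.

    The ionome table has one row per tissue x replicate x treatment x
    harvest (t0 is shared and emitted once, under treatment 'control'),
    with columns species, treatment, harvest, tissue, replicate,
    dry_weight and one ppm column per element.
    """
    rng = _rng(config.seed, "ionome")
    factor = _wd_concentration_factor(config)
    rows = []
    wd_harvests = [h for h in config.harvests if h != "t0"]
    for harvest in config.harvests:
        treatments = ["control"] if harvest == "t0" else ["control", "WD"]
        for treatment in treatments:
            for rep in range(1, config.n_replicates + 1):
                for tissue in config.tissues:
                    dw = config.baseline_dry_weight.loc[tissue, harvest]
                    dw = dw * _lognormal_noise(rng, config.noise_cv, None)
                    conc = config.baseline_concentration[tissue].copy()
                    if treatment == "WD":
                        conc = conc * factor[harvest]
                    conc = conc * _lognormal_noise(
                        rng, config.noise_cv, len(config.elements)
                    )
                    rows.append(
                        [config.species, treatment, harvest, tissue, rep, float(dw)]
                        + list(conc.to_numpy())
                    )
    samples = pd.DataFrame(
        rows,
        columns=["species", "treatment", "harvest", "tissue", "replicate",
                 "dry_weight"] + list(config.elements),
    )

    prng = _rng(config.seed, "phenotype")
    prow = []
    for harvest in wd_harvests:
        for treatment in ("control", "WD"):
            for rep in range(1, config.n_replicates + 1):
                rec = {"species": config.species, "treatment": treatment,
                       "harvest": harvest, "replicate": rep}
                for var, base in _PHENO_BASE.items():
                    eff = _PHENO_WD_EFFECT[var][harvest] if treatment == "WD" else 1.0
                    rec[var] = base * eff * _lognormal_noise(prng, config.noise_cv, None)
                rec["WUE"] = rec["A"] / rec["E"]
                prow.append(rec)
    phenotypes = pd.DataFrame(prow)

    truth = IonomeTruth(
        relative_nu=config.uptake_multiplier.copy(),
        concentration_ratio=factor,
    )
    return samples, phenotypes, truth


# ---------------------------------------------------------------------------
# RNA-seq count generator
# ---------------------------------------------------------------------------


@dataclass
class CountSimConfig:
    """Configuration of the synthetic NB count matrix."""

    n_genes: int = 2000
    n_samples_per_group: int = 5
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    dispersion: float = 0.1
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")


def gen_count_matrix(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, sample sheet, DE truth).

    Baseline relative abundances are lognormal; library sizes are drawn
    log-uniform over the configured range (so TMM is exercised
    nontrivially); planted DE genes carry +/- the configured log2FC in the
    WD group, balanced up/down. Counts are NB via gamma-Poisson mixing;
    dispersion 0 is the Poisson limit.
    """
    rng = _rng(config.seed, "counts")
    g, n = config.n_genes, config.n_samples_per_group
    genes = [f"gene{i:05d}" for i in range(1, g + 1)]
    samples = [f"ctrl_{j + 1}" for j in range(n)] + [f"wd_{j + 1}" for j in range(n)]
    groups = ["control"] * n + ["WD"] * n

    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=g)
    abundance /= abundance.sum()
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    lfc = np.zeros(g)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * config.planted_log2fc

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))
    if (lib <= 0).any():
        raise ValueError("zero library size")

    wd_abund = abundance * 2.0**lfc
    mu = np.empty((g, 2 * n))
    mu[:, :n] = abundance[:, None] * lib[None, :n]
    mu[:, n:] = wd_abund[:, None] * lib[None, n:]
    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=samples)
    sheet = pd.DataFrame({"sample": samples, "group": groups})
    truth = pd.DataFrame(
        {"gene": genes, "true_log2fc": lfc, "is_de": lfc != 0}
    ).set_index("gene")
    return counts_df, sheet, truth


# ---------------------------------------------------------------------------
# gene-element annotation generator
# ---------------------------------------------------------------------------


def gen_annotation(
    n_genes: int,
    elements: Sequence[str],
    per_element_counts: Mapping[str, int],
    kig_fraction: float = 0.5,
    seed: int = 0,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Random gene-element annotation table (gene, element, source).

    ``per_element_counts`` requests the number of annotated genes per
    element; ``kig_fraction`` of each element's rows are tagged KIG, the
    rest GO. Without ``allow_overlap`` the gene pools are disjoint across
    elements (counts must then sum to at most n_genes); with it, genes are
    drawn independently per element, so multi-element genes occur (one row
    per gene x element).
    """
    bad = set(per_element_counts) - set(elements)
    if bad:
        raise ValueError(f"unknown element symbols: {sorted(bad)}")
    if any(c < 0 for c in per_element_counts.values()):
        raise ValueError("per-element counts must be >= 0")
    total = sum(per_element_counts.values())
    if not allow_overlap and total > n_genes:
        raise ValueError(
            f"requested {total} disjoint annotations but only {n_genes} genes"
        )
    rng = _rng(seed, "annotation")
    genes = np.array([f"gene{i:05d}" for i in range(1, n_genes + 1)])
    rows = []
    if allow_overlap:
        for el in elements:
            c = per_element_counts.get(el, 0)
            if c == 0:
                continue
            chosen = rng.choice(genes, size=c, replace=False)
            n_kig = int(round(c * kig_fraction))
            for i, gname in enumerate(chosen):
                rows.append((gname, el, "KIG" if i < n_kig else "GO"))
    else:
        pool = rng.permutation(genes)
        start = 0
        for el in elements:
            c = per_element_counts.get(el, 0)
            if c == 0:
                continue
            chosen = pool[start:start + c]
            start += c
            n_kig = int(round(c * kig_fraction))
            for i, gname in enumerate(chosen):
                rows.append((gname, el, "KIG" if i < n_kig else "GO"))
    return pd.DataFrame(rows, columns=["gene", "element", "source"])


# ---------------------------------------------------------------------------
# plant image generator
# ---------------------------------------------------------------------------


def gen_plant_image(
    shapes: Sequence[Mapping],
    canvas: tuple[int, int] = (64, 64),
    pixel_scale: float = 1.0,
    background: tuple[int, int, int] = (20, 10, 5),
    seed: int = 0,
) -> tuple[ImageRecord, dict]:
    """Render simple shapes into an RGB image + mask with known areas.

    Each shape is a dict: ``{"type": "rect", "x", "y", "w", "h"}`` or
    ``{"type": "disk", "cx", "cy", "r"}``, plus an optional ``color``
    (default a leaf green). Returns the :class:`ImageRecord` and a truth
    dict with the pixel-counted ``projected_area`` and the
    ``convex_hull_area`` of the foreground pixel centers, both in cm^2,
    computed independently of the phenotyping module (scipy hull).
    """
    h, w = canvas
    mask = np.zeros((h, w), dtype=bool)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[..., 0], rgb[..., 1], rgb[..., 2] = background
    for spec in shapes:
        color = tuple(spec.get("color", (40, 160, 50)))
        kind = spec["type"]
        if kind == "rect":
            x, y, sw, sh = spec["x"], spec["y"], spec["w"], spec["h"]
            if x < 0 or y < 0 or x + sw > w or y + sh > h:
                raise ValueError(f"rect {spec} exceeds canvas {canvas}")
            sel = np.zeros_like(mask)
            sel[y:y + sh, x:x + sw] = True
        elif kind == "disk":
            cx, cy, r = spec["cx"], spec["cy"], spec["r"]
            if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
                raise ValueError(f"disk {spec} exceeds canvas {canvas}")
            yy, xx = np.mgrid[0:h, 0:w]
            sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        else:
            raise ValueError(f"unknown shape type {kind!r}")
        mask |= sel
        rgb[sel] = color
    if not mask.any():
        raise ValueError("requested image has an empty foreground mask")

    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    hull_area = 0.0
    if len(np.unique(pts, axis=0)) >= 3:
        try:
            from scipy.spatial import ConvexHull, QhullError

            hull_area = float(ConvexHull(pts).volume)  # 2-D "volume" is area
        except QhullError:  # collinear points
            hull_area = 0.0
    truth = {
        "projected_area": float(mask.sum()) * pixel_scale**2,
        "convex_hull_area": hull_area * pixel_scale**2,
    }
    return ImageRecord(rgb=rgb, mask=mask, pixel_scale=pixel_scale), truth
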