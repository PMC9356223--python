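"""Functional-ionome accounting under water deficit.

The ionome of a plant is described by the concentrations of 20 mineral
elements (macro-, micronutrients and beneficial elements) in each harvested
tissue. From destructive harvests this module derives:

* element quantity per tissue, ``Q = E x DW`` (ppm x g = ug);
* plant-total quantity, the sum of Q over the 3 (wheat: roots, OLB, YLB) or
  5 (rapeseed: + OP, YP) tissue types;
* accumulated net uptake between the pre-treatment harvest t0 and a later
  harvest t', ``NU = Q_plant(t') - Q_plant(t0)``, estimated over *all*
  subtractive combinations of replicate plant totals (5 x 5 replicates give
  n = 25 differences, reported as mean +/- SE with SE = sd / sqrt(25));
* treatment effects expressed relative to control, ``ratio = mean_WD /
  mean_control`` (applied alike to concentrations, NU, biomass, hormones);
* significance-masked relative tables for heatmap display (only cells with
  p < alpha keep their ratio).

Note on the combination SE: the 25 pairwise differences share replicates and
are therefore dependent; sd/sqrt(25) is the convention used for reporting.
``nu_significance(method="perm")`` offers a replicate-level permutation test
that respects the dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The 20 elements of the functional ionome, in the conventional order
#: (macronutrients, micronutrients, beneficial elements).
ELEMENTS: tuple[str, ...] = (
    "N", "Mg", "P", "S", "K", "Ca",
    "B", "Cl", "Mn", "Fe", "Ni", "Cu", "Zn", "Mo",
    "Na", "Co", "V", "Se", "Si", "Al",
)

#: Harvest codes: t0 = start of water deficit; t1/t2 = short/extended deficit
#: at 40% or 25% of field capacity.
HARVESTS: tuple[str, ...] = ("t0", "t1_40", "t1_25", "t2_40", "t2_25")
WD_HARVESTS: tuple[str, ...] = ("t1_40", "t1_25", "t2_40", "t2_25")

TISSUES_3: tuple[str, ...] = ("roots", "OLB", "YLB")
TISSUES_5: tuple[str, ...] = ("roots", "OLB", "OP", "YLB", "YP")

TREATMENTS: tuple[str, ...] = ("control", "WD")


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the supplied data."""


@dataclass
class IonomeSample:
    """One tissue of one replicate plant at one harvest."""

    species: str
    treatment: str
    harvest: str
    tissue: str
    replicate: int
    dry_weight: float
    concentrations: Mapping[str, float]  # element -> ppm (ug/g)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.harvest not in HARVESTS:
            raise ValueError(f"unknown harvest {self.harvest!r}")
        if self.dry_weight <= 0:
            raise ValueError(f"dry weight must be > 0 g, got {self.dry_weight}")
        for el, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {el}: {c}")

    def quantity(self, element: str) -> float:
        """Element quantity Q in this tissue (ug)."""
        return element_quantity(self.concentrations[element], self.dry_weight)


def element_quantity(concentration_ppm: float, dry_weight_g: float) -> float:
    """Quantity of an element in a tissue: Q = E x DW (ppm x g = ug)."""
    if not np.isfinite(concentration_ppm) or not np.isfinite(dry_weight_g):
        raise ValueError("inputs must be finite")
    if concentration_ppm < 0:
        raise ValueError(f"concentration must be >= 0 ppm, got {concentration_ppm}")
    if dry_weight_g <= 0:
        raise ValueError(f"dry weight must be > 0 g, got {dry_weight_g}")
    return concentration_ppm * dry_weight_g


def plant_total(
    samples: Iterable[IonomeSample], tissues: Optional[Sequence[str]] = None
) -> pd.Series:
    """Plant-total element quantities (ug) for one replicate plant.

    Sums Q over the expected tissue set (3 for wheat, 5 for rapeseed).
    Raises if a tissue is missing or duplicated.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples supplied")
    if tissues is None:
        tissues = TISSUES_5 if len(samples) == 5 else TISSUES_3
    seen = [s.tissue for s in samples]
    for t in tissues:
        if t not in seen:
            raise ValueError(f"missing tissue {t!r} for plant total")
    if len(seen) != len(set(seen)):
        raise ValueError(f"duplicate tissues in {seen}")
    elements = list(samples[0].concentrations)
    total = pd.Series(0.0, index=elements)
    for s in samples:
        for el in elements:
            total[el] += s.quantity(el)
    return total


@dataclass
class NetUptakeEstimate:
    """Accumulated net uptake of one element between t0 and t'.

    ``nu_values`` holds every subtractive combination q' - q0 over the
    Cartesian product of t' and t0 replicate plant totals (n1 x n2 values;
    25 for the full 5 + 5 design). ``se`` is sd/sqrt(n) over those values.
    """

    element: str
    treatment: str
    harvest: str
    nu_values: np.ndarray
    totals_t0: np.ndarray
    totals_tprime: np.ndarray
    mean: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self) -> None:
        self.nu_values = np.asarray(self.nu_values, dtype=float)
        self.totals_t0 = np.asarray(self.totals_t0, dtype=float)
        self.totals_tprime = np.asarray(self.totals_tprime, dtype=float)
        self.mean = float(self.nu_values.mean())
        n = self.nu_values.size
        self.se = float(self.nu_values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def n(self) -> int:
        return int(self.nu_values.size)


def net_uptake_combinations(
    totals_t0: Sequence[float],
    totals_tprime: Sequence[float],
    element: str = "",
    treatment: str = "",
    harvest: str = "",
) -> NetUptakeEstimate:
    """All subtractive combinations of plant totals between two harvests.

    nu_values = { q' - q0 : q' in totals_tprime, q0 in totals_t0 } over the
    full Cartesian product of replicates; 5 + 5 replicates give exactly 25.
    """
    t0 = np.asarray(list(totals_t0), dtype=float)
    tp = np.asarray(list(totals_tprime), dtype=float)
    if t0.size == 0 or tp.size == 0:
        raise ValueError("both replicate total lists must be non-empty")
    nu = (tp[:, None] - t0[None, :]).ravel()
    return NetUptakeEstimate(
        element=element, treatment=treatment, harvest=harvest,
        nu_values=nu, totals_t0=t0, totals_tprime=tp,
    )


def ratio_to_control(wd_mean: float, control_mean: float) -> float:
    """Treatment effect relative to control: mean_WD / mean_control."""
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; ratio undefined")
    return wd_mean / control_mean


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD post-hoc comparisons."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, diff, q, p_adj, significant
    alpha: float
    degenerate: bool = False


def anova_tukey(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> AnovaTukeyResult:
    """One-way ANOVA and Tukey HSD pairwise comparisons at level ``alpha``.

    Tukey-Kramer standard errors accommodate unbalanced groups; adjusted
    p-values come from the studentized-range distribution with k groups and
    N - k within degrees of freedom. If every group has zero internal
    variance the test is degenerate: p-values are NaN and ``degenerate`` is
    set, rather than reporting p = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [str(i) for i in range(k)]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    N = int(ns.sum())
    df_within = N - k
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    grand = float(np.concatenate(arrays).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    degenerate = ssw == 0.0
    rows = []
    if degenerate:
        f = np.nan
        p = np.nan
        for i, j in combinations(range(k), 2):
            rows.append((labels[i], labels[j], means[j] - means[i],
                         np.nan, np.nan, False))
    else:
        msw = ssw / df_within
        msb = ssb / (k - 1)
        f = msb / msw
        p = float(stats.f.sf(f, k - 1, df_within))
        for i, j in combinations(range(k), 2):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[j] - means[i]) / se
            if k == 2:
                # Q_{2,df} = sqrt(2)|t|: the Tukey p collapses to the F-test p
                p_adj = float(stats.f.sf(q**2 / 2.0, 1, df_within))
            else:
                p_adj = float(stats.studentized_range.sf(q, k, df_within))
            rows.append((labels[i], labels[j], means[j] - means[i],
                         q, p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(
        rows, columns=["group1", "group2", "diff", "q", "p_adj", "significant"]
    )
    return AnovaTukeyResult(
        f_statistic=float(f), p_value=p, pairwise=pairwise,
        alpha=alpha, degenerate=degenerate,
    )


def significance_mask(
    ratio_table: pd.DataFrame, p_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Mask a relative-to-control table by per-cell significance.

    Returns a long-format table with one row per cell of the input: the
    ratio, its p-value, a ``significant`` flag (p < alpha), the masked
    ratio (NaN where not significant — an explicit marker, cells are never
    dropped) and a ``direction`` annotation for heatmap coloring
    ('higher' for ratio > 1, 'lower' for ratio < 1, 'equal' at 1).
    """
    if ratio_table.shape != p_table.shape:
        raise ValueError(
            f"shape mismatch: ratios {ratio_table.shape} vs p-values {p_table.shape}"
        )
    if not ratio_table.index.equals(p_table.index) or not ratio_table.columns.equals(
        p_table.columns
    ):
        raise ValueError("ratio and p tables must share index and columns")
    ratios = ratio_table.stack(future_stack=True)
    ps = p_table.stack(future_stack=True)
    sig = ps < alpha
    direction = np.where(ratios > 1, "higher", np.where(ratios < 1, "lower", "equal"))
    out = pd.DataFrame({
        "ratio": ratios,
        "p_value": ps,
        "significant": sig,
        "masked_ratio": ratios.where(sig),
        "direction": direction,
    })
    out.index.set_names(["row", "col"], inplace=True)
    return out.reset_index()


def nu_significance(
    nu_wd: NetUptakeEstimate,
    nu_control: NetUptakeEstimate,
    alpha: float = 0.05,
    method: str = "welch",
    max_exact: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    n_resamples: int = 10_000,
) -> float:
    """p-value for a WD-vs-control difference in net uptake.

    method='welch'
        Welch two-sample t-test on the combination NU values. Simple, but
        treats the n1 x n2 differences as independent, which they are not.
    method='perm'
        Replicate-level permutation test: the t' plant totals of the two
        treatments are pooled and re-split in every possible way (exact
        enumeration up to ``max_exact`` splits, Monte-Carlo beyond); the
        statistic is the difference of mean NU. t0 totals are permuted the
        same way only when the two estimates carry distinct t0 samples
        (they are shared in the standard design).
    """
    a = nu_wd.nu_values
    b = nu_control.nu_values
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise DegenerateDataError("zero variance in both NU samples with unequal means")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue)
    if method != "perm":
        raise ValueError(f"unknown method {method!r}")

    tp_wd, tp_ct = nu_wd.totals_tprime, nu_control.totals_tprime
    t0_shared = (
        nu_wd.totals_t0.shape == nu_control.totals_t0.shape
        and np.allclose(np.sort(nu_wd.totals_t0), np.sort(nu_control.totals_t0))
    )
    obs = (tp_wd.mean() - nu_wd.totals_t0.mean()) - (
        tp_ct.mean() - nu_control.totals_t0.mean()
    )
    pooled = np.concatenate([tp_wd, tp_ct])
    n1 = tp_wd.size
    idx_all = np.arange(pooled.size)
    from math import comb

    n_splits = comb(pooled.size, n1)
    t0_term = 0.0 if t0_shared else (
        nu_control.totals_t0.mean() - nu_wd.totals_t0.mean()
    )
    count = 0
    total = 0
    if n_splits <= max_exact:
        for pick in combinations(idx_all, n1):
            pick = np.array(pick)
            rest = np.setdiff1d(idx_all, pick, assume_unique=True)
            stat = pooled[pick].mean() - pooled[rest].mean() + t0_term
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
            total += 1
    else:
        rng = rng or np.random.default_rng()
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            stat = perm[:n1].mean() - perm[n1:].mean() + t0_term
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
        count += 1  # include the observed split
        total = n_resamples + 1
    return count / total


# ---------------------------------------------------------------------------
# Model / Results interface over a tidy ionome table
# ---------------------------------------------------------------------------


class IonomeModel:
    """Net-uptake and relative-ionome analysis of a destructive-harvest study.

    Built from a tidy table with one row per (treatment, harvest, tissue,
    replicate) sample: columns ``species, treatment, harvest, tissue,
    replicate, dry_weight`` plus one concentration column (ppm) per element.
    The t0 harvest is shared by both treatments.

    ``fit()`` returns an :class:`IonomeResults` carrying per-element net
    uptake (mean +/- SE over all subtractive replicate combinations),
    WD/control relative tables for net uptake and tissue concentrations, and
    their significance masks.
    """

    REQUIRED = ["species", "treatment", "harvest", "tissue", "replicate", "dry_weight"]

    def __init__(self, data: pd.DataFrame, elements: Optional[Sequence[str]] = None):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.data = data.copy()
        if elements is None:
            elements = [c for c in data.columns if c in ELEMENTS]
        if not elements:
            raise ValueError("no element concentration columns found")
        self.elements = list(elements)
        if (self.data["dry_weight"] <= 0).any():
            bad = self.data.index[self.data["dry_weight"] <= 0].tolist()
            raise ValueError(f"non-positive dry weight in rows {bad}")
        neg = [e for e in self.elements if (self.data[e] < 0).any()]
        if neg:
            raise ValueError(f"negative concentrations for elements {neg}")
        self.tissues = sorted(self.data["tissue"].unique())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "IonomeModel":
        return cls(data, **kwargs)

    def plant_totals(self) -> pd.DataFrame:
        """Per-replicate plant-total quantities Q (ug) for every element.

        Index: (treatment, harvest, replicate); columns: elements.
        """
        df = self.data
        q = df[self.elements].multiply(df["dry_weight"], axis=0)
        q = pd.concat([df[["treatment", "harvest", "replicate", "tissue"]], q], axis=1)
        # every (treatment, harvest, replicate) must contribute each tissue once
        counts = q.groupby(["treatment", "harvest", "replicate"])["tissue"].agg(
            ["count", "nunique"]
        )
        bad = counts[counts["count"] != counts["nunique"]]
        if len(bad):
            raise ValueError(f"duplicated tissues for plants {bad.index.tolist()}")
        expected = counts["nunique"].max()
        incomplete = counts[counts["nunique"] != expected]
        if len(incomplete):
            raise ValueError(
                f"plants missing tissues (expected {expected}): "
                f"{incomplete.index.tolist()}"
            )
        return q.groupby(["treatment", "harvest", "replicate"])[self.elements].sum()

    def net_uptake(self) -> dict[tuple[str, str, str], NetUptakeEstimate]:
        """NetUptakeEstimate per (element, treatment, WD harvest)."""
        totals = self.plant_totals()
        t0 = totals.xs(("control", "t0"), level=("treatment", "harvest"))
        out: dict[tuple[str, str, str], NetUptakeEstimate] = {}
        for treatment in TREATMENTS:
            for harvest in WD_HARVESTS:
                try:
                    tp = totals.xs((treatment, harvest), level=("treatment", "harvest"))
                except KeyError:
                    continue
                for el in self.elements:
                    out[(el, treatment, harvest)] = net_uptake_combinations(
                        t0[el].to_numpy(), tp[el].to_numpy(),
                        element=el, treatment=treatment, harvest=harvest,
                    )
        return out

    def fit(
        self,
        alpha: float = 0.05,
        nu_test: str = "welch",
        seed: Optional[int] = None,
    ) -> "IonomeResults":
        estimates = self.net_uptake()
        rng = np.random.default_rng(seed)

        nu_rows = []
        for (el, trt, hv), est in estimates.items():
            nu_rows.append((el, trt, hv, est.mean, est.se, est.n))
        nu_table = pd.DataFrame(
            nu_rows, columns=["element", "treatment", "harvest", "mean", "se", "n"]
        )

        # relative NU (WD / control) with significance
        rel_rows = []
        for hv in WD_HARVESTS:
            for el in self.elements:
                wd = estimates.get((el, "WD", hv))
                ct = estimates.get((el, "control", hv))
                if wd is None or ct is None:
                    continue
                ratio = ratio_to_control(wd.mean, ct.mean)
                try:
                    p = nu_significance(wd, ct, alpha=alpha, method=nu_test, rng=rng)
                except DegenerateDataError:
                    p = np.nan  # noiseless data: test undefined, reported as NaN
                rel_rows.append((el, hv, ratio, p))
        rel_nu = pd.DataFrame(rel_rows, columns=["element", "harvest", "ratio", "p_value"])

        ratio_tab = rel_nu.pivot(index="element", columns="harvest", values="ratio")
        p_tab = rel_nu.pivot(index="element", columns="harvest", values="p_value")
        rel_nu_masked = significance_mask(ratio_tab, p_tab, alpha=alpha)
        rel_nu_masked = rel_nu_masked.rename(columns={"row": "element", "col": "harvest"})

        # relative tissue concentrations (WD / control per tissue x harvest)
        conc_rows = []
        df = self.data
        for hv in WD_HARVESTS:
            for tissue in self.tissues:
                sel = (df["harvest"] == hv) & (df["tissue"] == tissue)
                wd_g = df[sel & (df["treatment"] == "WD")]
                ct_g = df[sel & (df["treatment"] == "control")]
                if len(wd_g) < 2 or len(ct_g) < 2:
                    continue
                for el in self.elements:
                    ct_mean = ct_g[el].mean()
                    if ct_mean == 0:
                        continue
                    ratio = ratio_to_control(wd_g[el].mean(), ct_mean)
                    res = anova_tukey(
                        [ct_g[el].to_numpy(), wd_g[el].to_numpy()],
                        alpha=alpha, labels=["control", "WD"],
                    )
                    p = res.pairwise["p_adj"].iloc[0]
                    conc_rows.append((el, tissue, hv, ratio, p))
        rel_conc = pd.DataFrame(
            conc_rows, columns=["element", "tissue", "harvest", "ratio", "p_value"]
        )
        if len(rel_conc):
            rel_conc["significant"] = rel_conc["p_value"] < alpha
            rel_conc["masked_ratio"] = rel_conc["ratio"].where(rel_conc["significant"])

        return IonomeResults(
            model=self, alpha=alpha, nu_test=nu_test,
            estimates=estimates, net_uptake_table=nu_table,
            relative_nu=rel_nu_masked, relative_concentration=rel_conc,
        )


@dataclass
class IonomeResults:
    """Fitted ionome analysis: net uptake, relative tables, significance."""

    model: IonomeModel
    alpha: float
    nu_test: str
    estimates: dict
    net_uptake_table: pd.DataFrame
    relative_nu: pd.DataFrame
    relative_concentration: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Ionome net-uptake analysis",
            "=" * 60,
            f"elements: {len(self.model.elements)}  tissues: {len(self.model.tissues)}"
            f"  alpha: {self.alpha}  NU test: {self.nu_test}",
            "",
            "Relative net uptake (WD / control), masked at p < alpha:",
        ]
        tab = self.relative_nu.pivot(
            index="element", columns="harvest", values="masked_ratio"
        )
        # keep study harvest order where present
        cols = [h for h in WD_HARVESTS if h in tab.columns]
        lines.append(tab[cols].round(3).to_string())
        n_sig = int(self.relative_nu["significant"].sum())
        lines.append("")
        lines.append(
            f"{n_sig} / {len(self.relative_nu)} element x harvest NU ratios "
            f"significant at alpha = {self.alpha}"
        )
        return "\n".join(lines)
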