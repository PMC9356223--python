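"""Bulk RNA-seq differential expression: TMM, NB GLM, LRT, BH.

The stage mirrors the standard edgeR-style workflow for two-group
(water-deficit vs control) comparisons of an integer gene x sample count
matrix:

1. remove genes with low expression (CPM >= threshold in >= min_samples);
2. between-library normalization by the trimmed mean of M-values (TMM):
   per-sample scale factors from a doubly trimmed, precision-weighted mean
   of per-gene log ratios against a reference library, renormalized to
   geometric mean 1;
3. a common negative-binomial dispersion phi estimated by maximizing the
   profile likelihood over genes (phi = 0 is the Poisson limit);
4. per-gene log-link NB GLM with offset log(library size x factor); the
   group coefficient is tested with a likelihood-ratio test against
   chi-square(1); log2 fold change = coefficient / ln 2;
5. Benjamini-Hochberg adjustment per contrast; a gene is called
   differentially expressed when adjusted p <= alpha, with no fold-change
   cutoff.

The NB likelihood is parameterized as Var(Y) = mu + phi * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_low_expression",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_glm_lrt",
    "bh_adjust",
    "call_degs",
    "DEModel",
    "DEResults",
]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_low_expression(
    counts: pd.DataFrame, cpm_threshold: float = 1.0, min_samples: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Keep genes with CPM >= ``cpm_threshold`` in >= ``min_samples`` samples.

    Returns the filtered matrix and a report dict with kept/removed counts
    and fractions.
    """
    if cpm_threshold < 0:
        raise ValueError("cpm_threshold must be >= 0")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"libraries with zero total counts: {bad}")
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm >= cpm_threshold).sum(axis=1) >= min_samples
    if cpm_threshold == 0:
        keep[:] = True  # identity filter
    filtered = counts.loc[keep]
    n = len(counts)
    report = {
        "n_input": n,
        "n_kept": int(keep.sum()),
        "n_removed": int(n - keep.sum()),
        "fraction_removed": float((n - keep.sum()) / n) if n else 0.0,
        "cpm_threshold": cpm_threshold,
        "min_samples": min_samples,
    }
    return filtered, report


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors (geometric mean 1) and library sizes."""

    factors: pd.Series
    library_sizes: pd.Series
    reference: str

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


def _tmm_pair(
    y: np.ndarray, y_ref: np.ndarray, n: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor (log2 scale) of one library against the reference."""
    ok = (y > 0) & (y_ref > 0)
    if not ok.any():
        raise ValueError("library shares no positively expressed gene with reference")
    p, p_ref = y[ok] / n, y_ref[ok] / n_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # delta-method variance of M; weights are its inverse (precision)
    v = (n - y[ok]) / (n * y[ok]) + (n_ref - y_ref[ok]) / (n_ref * y_ref[ok])
    if np.max(np.abs(m)) < 1e-6:  # identical composition: factor exactly 1
        return 0.0
    cnt = m.size
    lo_m = np.floor(cnt * trim_m) + 1
    hi_m = cnt - np.floor(cnt * trim_m)
    lo_a = np.floor(cnt * trim_a) + 1
    hi_a = cnt - np.floor(cnt * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise ValueError("trimming removed every gene; lower the trim fractions")
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: Optional[str] = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    ``trim_m`` and ``trim_a`` are the two-sided trim fractions on the
    log-ratio (M) and average-abundance (A) scales. The reference library
    defaults to the sample whose upper quartile of CPM is closest to the
    mean upper quartile. Factors are renormalized to geometric mean 1.
    """
    if not (0 <= trim_m < 0.5) or not (0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total")
    mat = counts.to_numpy(dtype=float)
    if ref is None:
        # upper quartile of the scaled counts (zeros included), reference =
        # library closest to the mean upper quartile
        uq = np.quantile(mat / lib.to_numpy()[None, :], 0.75, axis=0)
        ref = counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    j_ref = counts.columns.get_loc(ref)
    y_ref, n_ref = mat[:, j_ref], lib.iloc[j_ref]
    logf = np.array([
        _tmm_pair(mat[:, j], y_ref, lib.iloc[j], n_ref, trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_sizes=lib,
        reference=str(ref),
    )


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized over genes)
# ---------------------------------------------------------------------------


def _fit_log_mean(y: np.ndarray, offsets: np.ndarray, phi: float) -> np.ndarray:
    """MLE of b in mu_j = exp(b) * s_j for an NB(mu, phi) sample, per gene.

    ``y`` is (genes, samples); ``offsets`` s_j are the effective library
    sizes. Newton iteration on the (concave) log-likelihood; genes whose
    counts are all zero get b = -inf (mu = 0).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(offsets, dtype=float)
    tot = y.sum(axis=1)
    with np.errstate(divide="ignore"):
        b = np.log(tot / s.sum())  # Poisson MLE as start; -inf where tot == 0
    active = tot > 0
    if phi > 0 and active.any():
        ba = b[active].copy()
        ya = y[active]
        for _ in range(100):
            mu = np.exp(ba)[:, None] * s[None, :]
            denom = 1.0 + phi * mu
            score = ((ya - mu) / denom).sum(axis=1)
            info = (mu * (1.0 + phi * ya) / denom**2).sum(axis=1)
            step = score / info
            np.clip(step, -5.0, 5.0, out=step)
            ba += step
            if np.max(np.abs(step)) < 1e-12:
                break
        b[active] = ba
    return b


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB (or Poisson when phi = 0) log-likelihood, summed over samples."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = y * np.log(mu) - mu
        term = np.where((y == 0) & (mu == 0), 0.0, term)
        return (term - gammaln(y + 1)).sum(axis=1)
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    term = np.where((y == 0) & (mu == 0), 0.0, term)
    return term.sum(axis=1)


def _group_loglik(
    counts: np.ndarray, group_idx: Sequence[np.ndarray],
    offsets: np.ndarray, phi: float, adjusted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood and per-group log-mean coefficients of the full model.

    With ``adjusted=True`` the Cox-Reid adjustment -0.5*log|I| for the
    profiled-out mean parameters is included (the plain profile likelihood
    underestimates the dispersion because every gene absorbs one mean per
    group); the information is diagonal for a group-indicator design,
    I_g = sum_j mu_j / (1 + phi*mu_j).
    """
    n_genes = counts.shape[0]
    ll = np.zeros(n_genes)
    coefs = np.zeros((n_genes, len(group_idx)))
    for g, idx in enumerate(group_idx):
        y = counts[:, idx]
        s = offsets[idx]
        b = _fit_log_mean(y, s, phi)
        with np.errstate(over="ignore"):
            mu = np.exp(b)[:, None] * s[None, :]
        mu = np.where(np.isfinite(mu), mu, 0.0)
        ll += _nb_loglik(y, mu, phi)
        if adjusted:
            info = (mu / (1.0 + phi * mu)).sum(axis=1)
            with np.errstate(divide="ignore"):
                adj = 0.5 * np.log(info)
            ll -= np.where(info > 0, adj, 0.0)  # all-zero groups carry no info
        coefs[:, g] = b
    return ll, coefs


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[str],
    factors: Optional[NormalizationFactors] = None,
    phi_max: float = 5.0,
) -> float:
    """Common NB dispersion phi maximizing the adjusted profile likelihood.

    Group means are profiled out (re-fitted at every candidate phi) with a
    Cox-Reid adjustment for the estimated means; the 1-D maximization runs
    on log(phi). Returns 0.0 (the Poisson limit) when
    the optimum collapses to the lower boundary. Groups with a single
    replicate are rejected: they carry no within-group information.
    """
    groups = np.asarray(groups)
    labels, counts_per = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts_per < 2).any():
        bad = labels[counts_per < 2].tolist()
        raise ValueError(
            f"groups with a single replicate cannot inform dispersion: {bad}"
        )
    mat = counts.to_numpy(dtype=float)
    if factors is None:
        offsets = mat.sum(axis=0)
    else:
        offsets = factors.effective_library_sizes.to_numpy(dtype=float)
    group_idx = [np.where(groups == lab)[0] for lab in labels]

    def neg_profile(log_phi: float) -> float:
        ll, _ = _group_loglik(
            mat, group_idx, offsets, float(np.exp(log_phi)), adjusted=True
        )
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        neg_profile, bounds=(np.log(1e-6), np.log(phi_max)), method="bounded",
        options={"xatol": 1e-4},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"dispersion estimation did not converge: {res.message}")
    phi_hat = float(np.exp(res.x))
    ll_boundary, _ = _group_loglik(mat, group_idx, offsets, 0.0, adjusted=True)
    if -res.fun <= float(ll_boundary.sum()) + 1e-8 or phi_hat <= 2e-6:
        return 0.0
    return phi_hat


def nb_glm_lrt(
    counts: pd.DataFrame,
    groups: Sequence[str],
    factors: Optional[NormalizationFactors] = None,
    dispersion: float = 0.0,
    reference_group: str = "control",
) -> pd.DataFrame:
    """Per-gene two-group NB GLM with likelihood-ratio test.

    Fits log mu_gj = b_g(group_j) + log(offset_j) per gene and tests the
    group effect with 2*(ll_full - ll_null) against chi-square(1).
    log2FC is the group-coefficient difference (treatment minus
    ``reference_group``) divided by ln 2; groups whose counts are all zero
    are shrunk with a half-count for fold-change reporting only. Genes with
    zero counts everywhere get p = 1, log2FC = 0 and ``all_zero`` set.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.tolist()}")
    if reference_group not in labels:
        reference_group = labels[0]
    other = labels[labels != reference_group][0]
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    if factors is None:
        offsets = mat.sum(axis=0)
    else:
        offsets = factors.effective_library_sizes.to_numpy(dtype=float)
    order = [reference_group, other]
    group_idx = [np.where(groups == lab)[0] for lab in order]

    ll_full, coefs = _group_loglik(mat, group_idx, offsets, dispersion)
    b_null = _fit_log_mean(mat, offsets, dispersion)
    with np.errstate(over="ignore"):
        mu_null = np.exp(b_null)[:, None] * offsets[None, :]
    mu_null = np.where(np.isfinite(mu_null), mu_null, 0.0)
    ll_null = _nb_loglik(mat, mu_null, dispersion)

    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)

    # fold-change reporting: replace -inf coefficients by a half-count shrink
    b_rep = coefs.copy()
    for g, idx in enumerate(group_idx):
        zero = ~np.isfinite(b_rep[:, g])
        if zero.any():
            b_rep[zero, g] = np.log(0.5 / offsets[idx].sum())
    log2fc = (b_rep[:, 1] - b_rep[:, 0]) / np.log(2.0)

    all_zero = mat.sum(axis=1) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    log2fc = np.where(all_zero, 0.0, log2fc)

    return pd.DataFrame(
        {
            "gene": counts.index,
            "log2FC": log2fc,
            "p_value": pvals,
            "all_zero": all_zero,
        }
    ).set_index("gene")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag differentially expressed genes at adjusted p <= alpha.

    No fold-change cutoff is applied; direction comes from the sign of
    log2FC. Adds (or recomputes) the ``p_adj`` column with BH if absent.
    """
    out = results.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out["deg"] = out["p_adj"] <= alpha
    out["direction"] = np.where(out["log2FC"] > 0, "up",
                                np.where(out["log2FC"] < 0, "down", "none"))
    return out


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class DEModel:
    """Differential expression of WD vs control from a count matrix.

    Parameters
    ----------
    counts : gene x sample DataFrame of non-negative integers.
    sample_sheet : DataFrame with columns ``sample`` and ``group``
        (values 'control' / 'WD'); an optional ``harvest`` column splits the
        analysis into one WD-vs-control contrast per harvest.

    ``fit()`` filters low-expression genes, computes TMM factors and a
    common dispersion, runs the per-gene NB GLM LRT for every contrast and
    adjusts p-values with BH per contrast.
    """

    def __init__(self, counts: pd.DataFrame, sample_sheet: pd.DataFrame):
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        required = {"sample", "group"}
        if not required.issubset(sample_sheet.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        sheet = sample_sheet.set_index("sample")
        missing = [s for s in counts.columns if s not in sheet.index]
        if missing:
            raise ValueError(f"samples absent from sheet: {missing}")
        self.counts = counts.astype(float)
        self.sheet = sheet.loc[counts.columns]
        bad = set(self.sheet["group"]) - {"control", "WD"}
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}; expected control/WD")

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, sample_sheet: pd.DataFrame
    ) -> "DEModel":
        return cls(counts, sample_sheet)

    def contrasts(self) -> dict[str, pd.Index]:
        """Sample selections, one WD-vs-control contrast per harvest."""
        if "harvest" in self.sheet.columns:
            out = {}
            for hv in pd.unique(self.sheet["harvest"]):
                sel = self.sheet.index[self.sheet["harvest"] == hv]
                grp = self.sheet.loc[sel, "group"]
                if (grp == "control").sum() >= 2 and (grp == "WD").sum() >= 2:
                    out[str(hv)] = sel
            if not out:
                raise ValueError("no harvest with >= 2 samples per group")
            return out
        return {"WD_vs_control": self.sheet.index}

    def fit(
        self,
        alpha: float = 0.05,
        cpm_threshold: float = 1.0,
        min_samples: int = 2,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        dispersion: Optional[float] = None,
    ) -> "DEResults":
        filtered, report = filter_low_expression(
            self.counts, cpm_threshold=cpm_threshold, min_samples=min_samples
        )
        norm = tmm_factors(filtered, trim_m=trim_m, trim_a=trim_a)
        tables: dict[str, pd.DataFrame] = {}
        dispersions: dict[str, float] = {}
        for name, samples in self.contrasts().items():
            sub = filtered[samples]
            grp = self.sheet.loc[samples, "group"].to_numpy()
            sub_norm = NormalizationFactors(
                factors=norm.factors[samples],
                library_sizes=norm.library_sizes[samples],
                reference=norm.reference,
            )
            phi = (
                estimate_common_dispersion(sub, grp, sub_norm)
                if dispersion is None
                else float(dispersion)
            )
            res = nb_glm_lrt(sub, grp, sub_norm, dispersion=phi)
            res["p_adj"] = bh_adjust(res["p_value"].to_numpy())
            tables[name] = call_degs(res, alpha=alpha)
            dispersions[name] = phi
        return DEResults(
            model=self, alpha=alpha, tables=tables,
            normalization=norm, dispersions=dispersions, filter_report=report,
        )


@dataclass
class DEResults:
    """Fitted differential-expression analysis."""

    model: DEModel
    alpha: float
    tables: dict
    normalization: NormalizationFactors
    dispersions: dict
    filter_report: dict

    def deg_sets(self, direction: Optional[str] = None) -> dict[str, set]:
        """DEG gene-id sets per contrast, optionally split by direction."""
        out = {}
        for name, tab in self.tables.items():
            sel = tab["deg"]
            if direction is not None:
                sel = sel & (tab["direction"] == direction)
            out[name] = set(tab.index[sel])
        return out

    def summary(self) -> str:
        rep = self.filter_report
        lines = [
            "Negative-binomial differential expression (TMM + GLM LRT + BH)",
            "=" * 64,
            f"genes: {rep['n_input']} input, {rep['n_kept']} kept after CPM filter "
            f"(removed {rep['fraction_removed']:.1%})",
            f"TMM reference library: {self.normalization.reference}",
            f"DEG call: adjusted p <= {self.alpha}, no fold-change cutoff",
            "",
            f"{'contrast':<16}{'dispersion':>12}{'DEGs':>8}{'up':>6}{'down':>6}",
        ]
        for name, tab in self.tables.items():
            n_deg = int(tab["deg"].sum())
            n_up = int((tab["deg"] & (tab["direction"] == "up")).sum())
            n_dn = int((tab["deg"] & (tab["direction"] == "down")).sum())
            lines.append(
                f"{name:<16}{self.dispersions[name]:>12.4f}{n_deg:>8}{n_up:>6}{n_dn:>6}"
            )
        return "\n".join(lines)
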