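"""Negative-binomial GLM differential expression.

Three analyses over the 4-group diel heat-shock design are supported:

* ``analysis1_AM`` / ``analysis1_PM`` — per-time two-group models
  (``~ condition``) fit on the AM or PM samples only;
* ``analysis2`` — a four-group cell-means model with the contrasts
  AM heat vs AM control, PM heat vs PM control, and AM control vs
  PM control (the inputs of the refined gating categorization);
* ``analysis3`` — the interaction model ``~ condition + time +
  condition:time`` whose interaction coefficient tests whether the heat
  effect differs between AM and PM.

Each gene is fit by iteratively reweighted least squares on a log-link NB
GLM with log size-factor offsets and a plug-in gene-wise dispersion.  The
dispersion is a per-group method-of-moments estimate pooled across groups
and shrunk toward a fitted mean-dispersion trend.  Contrasts are tested
with Wald statistics against the standard normal and adjusted per contrast
with Benjamini-Hochberg.  Reported fold changes are plain (unshrunk) log2
estimates, matching how downstream significance cutoffs are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, Thresholds, ValidationError, size_factors

LN2 = float(np.log(2.0))

ANALYSIS_NAMES = ("analysis1_AM", "analysis1_PM", "analysis2", "analysis3")


@dataclass
class DesignSpec:
    """A design matrix builder plus named contrast vectors.

    ``coef_names`` label the columns of the design matrix produced by
    :func:`build_design_matrix`; each contrast is a vector of the same
    width whose dot product with the coefficient vector is the tested
    log2 effect.
    """

    name: str
    coef_names: list[str]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cname, vec in self.contrasts.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.coef_names),):
                raise ValidationError(
                    f"contrast {cname!r} has width {vec.shape}, design has "
                    f"{len(self.coef_names)} coefficients"
                )
            self.contrasts[cname] = vec


def make_design(name: str) -> DesignSpec:
    """Return the DesignSpec for one of the named analyses."""
    if name in ("analysis1_AM", "analysis1_PM"):
        return DesignSpec(
            name,
            coef_names=["intercept", "heat"],
            contrasts={"heat_vs_control": np.array([0.0, 1.0])},
        )
    if name == "analysis2":
        return DesignSpec(
            name,
            coef_names=list(("AM_control", "AM_heat", "PM_control", "PM_heat")),
            contrasts={
                "AMheat_vs_AMctrl": np.array([-1.0, 1.0, 0.0, 0.0]),
                "PMheat_vs_PMctrl": np.array([0.0, 0.0, -1.0, 1.0]),
                "AMctrl_vs_PMctrl": np.array([1.0, 0.0, -1.0, 0.0]),
            },
        )
    if name == "analysis3":
        return DesignSpec(
            name,
            coef_names=["intercept", "heat", "PM", "heat_PM"],
            contrasts={"interaction": np.array([0.0, 0.0, 0.0, 1.0])},
        )
    raise ValidationError(f"unknown analysis {name!r}; expected one of {ANALYSIS_NAMES}")


def build_design_matrix(samples: pd.DataFrame, design: DesignSpec) -> np.ndarray:
    """Design matrix (samples x coefficients) for the given spec."""
    heat = (samples["condition"] == "heat").to_numpy(dtype=float)
    pm = (samples["time"] == "PM").to_numpy(dtype=float)
    n = len(samples)
    if design.name.startswith("analysis1"):
        time = design.name.split("_")[1]
        if not (samples["time"] == time).all():
            raise ValidationError(
                f"{design.name} expects only {time} samples"
            )
        return np.column_stack([np.ones(n), heat])
    if design.name == "analysis2":
        return np.column_stack(
            [
                (1 - pm) * (1 - heat),
                (1 - pm) * heat,
                pm * (1 - heat),
                pm * heat,
            ]
        )
    if design.name == "analysis3":
        return np.column_stack([np.ones(n), heat, pm, heat * pm])
    raise ValidationError(f"unknown design {design.name!r}")


@dataclass
class DEResult:
    """Per-gene test results for one named contrast.

    ``table`` columns: ``baseMean`` (mean normalized count), ``log2FC``,
    ``SE`` (log2 scale), ``stat`` (Wald z), ``p``, ``padj`` (BH within the
    contrast), ``alpha`` (dispersion used) and ``converged``.
    """

    contrast: str
    analysis: str
    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, thresholds: Thresholds) -> pd.Series:
        """Dual-threshold call: padj < cut and |log2FC| > cut."""
        t = self.table
        return (t["padj"] < thresholds.padj_cut) & (
            t["log2FC"].abs() > thresholds.lfc_cut
        )

    def write(self, path, meta: dict | None = None) -> None:
        from .core import write_tsv

        meta = {"contrast": self.contrast, "analysis": self.analysis, **(meta or {})}
        write_tsv(self.table.reset_index(), path, meta)


# ---------------------------------------------------------------------------
# Dispersion estimation


def estimate_dispersions(
    m: CountMatrix,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
    alpha_floor: float = 1e-8,
    fixed_alpha: float | None = None,
) -> pd.Series:
    """Gene-wise NB dispersion (``var = mu + alpha mu^2``) estimates.

    Per experimental group, a method-of-moments estimate
    ``(var - mean) / mean^2`` is computed on size-factor-normalized counts
    and pooled across groups weighted by residual degrees of freedom.  The
    pooled raw values are then shrunk toward a parametric trend
    ``a / mu + b`` fitted across genes (weighted average with weight
    ``shrink_weight`` on the trend), stabilising the noisy per-gene
    estimates at small replicate numbers.

    A single-replicate design carries no within-group information and is
    rejected unless ``fixed_alpha`` supplies the dispersion directly.
    """
    if fixed_alpha is not None:
        return pd.Series(
            np.full(m.n_genes, max(fixed_alpha, alpha_floor)), index=m.genes,
            name="alpha",
        )
    groups = m.group_labels()
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValidationError(
            "dispersion estimation needs >= 2 replicates in some group "
            "(or pass fixed_alpha)"
        )
    if factors is None:
        factors = size_factors(m)
    q = (m.counts / factors.loc[m.sample_ids]).to_numpy()

    num = np.zeros(m.n_genes)
    den = np.zeros(m.n_genes)
    base = np.zeros(m.n_genes)
    total = 0
    for label in sizes.index:
        idx = (groups == label).to_numpy()
        n_j = int(idx.sum())
        if n_j < 2:
            continue
        sub = q[:, idx]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_j = (var - mean) / np.square(mean)
        a_j = np.where(np.isfinite(a_j), a_j, 0.0)
        w = n_j - 1
        num += w * a_j
        den += w
        base += n_j * mean
        total += n_j
    raw = np.clip(num / den, alpha_floor, None)
    mu = base / total

    trend = _fit_dispersion_trend(mu, raw, alpha_floor)
    alpha = shrink_weight * trend + (1.0 - shrink_weight) * raw
    return pd.Series(np.clip(alpha, alpha_floor, None), index=m.genes, name="alpha")


def _fit_dispersion_trend(
    mu: np.ndarray, raw: np.ndarray, alpha_floor: float
) -> np.ndarray:
    """Least-squares fit of ``alpha ~ a / mu + b`` with a, b >= 0."""
    ok = (mu > 0) & np.isfinite(raw)
    if ok.sum() < 2:
        return np.full_like(raw, max(np.median(raw[ok]) if ok.any() else alpha_floor, alpha_floor))
    X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    from scipy.optimize import nnls

    coef, _ = nnls(X, raw[ok])
    a, b = coef
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a / mu + b, b)
    return np.clip(trend, alpha_floor, None)


# ---------------------------------------------------------------------------
# GLM fitting


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-10,
):
    """Vectorized per-gene IRLS for the NB log-link GLM.

    Y: (G, S) counts; X: (S, P) design; offset: (S,) log size factors;
    alpha: (G,) dispersions.  Returns (beta (G, P) natural-log scale,
    cov (G, P, P), converged (G,)).  The linear predictor is clamped to
    keep separated fits (a group with all-zero counts) finite.
    """
    G, S = Y.shape
    P = X.shape[1]
    # initialise from a least-squares fit to log pseudo-counts
    z0 = np.log((Y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, P)
    eye = ridge * np.eye(P)

    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        eta = np.clip(b @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[idx, None] * mu)  # (g, S)
        z = (eta - offset[None, :]) + (Y[idx] - mu) / mu
        XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + eye[None, :, :]
        XtWz = np.einsum("sp,gs,gs->gp", X, W, z)
        b_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(b_new - b).max(axis=1)
        beta[idx] = b_new
        done = step < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("sp,gs,sq->gpq", X, W, X) + (ridge * np.eye(P))[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are propagated
    and excluded from the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def fit_and_test(
    m: CountMatrix,
    design: DesignSpec,
    thresholds: Thresholds | None = None,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    fixed_alpha: float | None = None,
) -> dict[str, DEResult]:
    """Fit the NB GLM and Wald-test every contrast of ``design``.

    Returns one :class:`DEResult` per contrast.  Genes whose IRLS fit does
    not converge are flagged, their p set missing and excluded from the BH
    adjustment.
    """
    thresholds = thresholds or Thresholds()
    if factors is None:
        factors = size_factors(m)
    if dispersions is None:
        dispersions = estimate_dispersions(m, factors, fixed_alpha=fixed_alpha)
    dispersions = dispersions.loc[m.genes]

    X = build_design_matrix(m.samples, design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"design matrix for {design.name} is rank-deficient")
    Y = m.counts.to_numpy(dtype=float)
    offset = np.log(factors.loc[m.sample_ids].to_numpy(dtype=float))
    alpha = dispersions.to_numpy(dtype=float)

    beta, cov, converged = _irls_nb(Y, X, offset, alpha)
    base_mean = (Y / np.exp(offset)[None, :]).mean(axis=1)

    results: dict[str, DEResult] = {}
    for cname, c in design.contrasts.items():
        lfc_nat = beta @ c
        se_nat = np.sqrt(np.einsum("p,gpq,q->g", c, cov, c))
        log2fc = lfc_nat / LN2
        se2 = se_nat / LN2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = lfc_nat / se_nat
        p = 2.0 * stats.norm.sf(np.abs(stat))
        p = np.where(converged, p, np.nan)
        padj = bh_adjust(p)
        table = pd.DataFrame(
            {
                "baseMean": base_mean,
                "log2FC": log2fc,
                "SE": se2,
                "stat": stat,
                "p": p,
                "padj": padj,
                "alpha": alpha,
                "converged": converged,
            },
            index=m.genes,
        )
        results[cname] = DEResult(contrast=cname, analysis=design.name, table=table)
    return results


# ---------------------------------------------------------------------------
# Convenience wrappers for the three named analyses


def run_analysis1(
    m: CountMatrix, thresholds: Thresholds | None = None, **kw
) -> dict[str, DEResult]:
    """Per-time two-group analysis; returns {'AM': ..., 'PM': ...}."""
    out = {}
    for time in ("AM", "PM"):
        sub = m.subset_samples(m.samples["time"] == time)
        design = make_design(f"analysis1_{time}")
        res = fit_and_test(sub, design, thresholds, **kw)
        out[time] = res["heat_vs_control"]
    return out


def run_analysis2(
    m: CountMatrix, thresholds: Thresholds | None = None, **kw
) -> dict[str, DEResult]:
    """Four-group cell-means analysis with the three gating contrasts."""
    return fit_and_test(m, make_design("analysis2"), thresholds, **kw)


def run_analysis3(
    m: CountMatrix, thresholds: Thresholds | None = None, **kw
) -> DEResult:
    """Interaction analysis; returns the condition-by-time DEResult."""
    res = fit_and_test(m, make_design("analysis3"), thresholds, **kw)
    return res["interaction"]
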