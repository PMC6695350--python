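"""Synthetic two-timepoint heat-shock count experiments with ground truth.

The generator emulates the structure of a diel heat-shock RNA-seq study:
four experimental groups (AM/PM x control/heat) with replicated samples,
negative-binomial counts, per-sample library-size factors, diel differences
in basal (control) expression, and time-gated heat responses drawn from the
eighteen archetypes of the refined gating categorization (plus a pure-null
archetype and a "discordant" archetype that responds in opposite directions
at the two times of day).

Every simulated gene carries a ground-truth row (archetype, basal and heat
effect sizes, baseline mean, dispersion) so downstream stages can be scored
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CountMatrix, ValidationError

#: archetype -> (basal sign, AM heat sign, PM heat sign)
#: basal is the log2 difference AM control minus PM control;
#: heat signs are the per-time log2 heat effects.
ARCHETYPE_SIGNS: dict[str, tuple[int, int, int]] = {
    # basal higher in AM (categories 1-6)
    "cat1": (+1, +1, 0),
    "cat2": (+1, -1, 0),
    "cat3": (+1, 0, +1),
    "cat4": (+1, 0, -1),
    "cat5": (+1, +1, +1),
    "cat6": (+1, -1, -1),
    # basal higher in PM (categories 7-12)
    "cat7": (-1, +1, 0),
    "cat8": (-1, -1, 0),
    "cat9": (-1, 0, +1),
    "cat10": (-1, 0, -1),
    "cat11": (-1, +1, +1),
    "cat12": (-1, -1, -1),
    # equal basal (categories 13-18)
    "cat13": (0, +1, 0),
    "cat14": (0, -1, 0),
    "cat15": (0, 0, +1),
    "cat16": (0, 0, -1),
    "cat17": (0, +1, +1),
    "cat18": (0, -1, -1),
    # not part of the 18-category grid
    "null": (0, 0, 0),
    "discordant": (0, -1, +1),  # heat-repressed in AM, heat-induced in PM
}


def default_archetype_proportions() -> dict[str, float]:
    """Mixture emulating a genome-scale screen: ~27% responsive genes spread
    evenly over the 18 archetypes, 1% discordant responders, the rest null."""
    props = {f"cat{i}": 0.015 for i in range(1, 19)}
    props["discordant"] = 0.01
    props["null"] = 1.0 - sum(props.values())
    return props


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``basal_log2fc`` and ``heat_log2fc`` are positive effect magnitudes in
    log2 units; signs come from the archetype.  ``baseline_log_mean`` and
    ``dispersion_log_mean`` are (mu, sigma) of natural-log-normal draws for
    the per-gene control mean and NB dispersion alpha (variance model
    ``var = mu + alpha * mu**2``).  ``libsize_range`` bounds log-uniform
    multiplicative library-size factors.
    """

    n_genes: int = 2000
    replicates: int = 4
    archetype_proportions: dict[str, float] = field(
        default_factory=default_archetype_proportions
    )
    basal_log2fc: float = 2.0
    heat_log2fc: float = 2.0
    baseline_log_mean: tuple[float, float] = (5.0, 2.0)
    dispersion_log_mean: tuple[float, float] = (float(np.log(0.05)), 0.5)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        total = sum(self.archetype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"archetype proportions must sum to 1 (got {total})"
            )
        unknown = set(self.archetype_proportions) - set(ARCHETYPE_SIGNS)
        if unknown:
            raise ValidationError(f"unknown archetype(s): {sorted(unknown)}")
        if self.basal_log2fc <= 0 or self.heat_log2fc <= 0:
            raise ValidationError("effect magnitudes must be > 0")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValidationError("libsize_range must satisfy 0 < low <= high")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("baseline_log_mean", "dispersion_log_mean", "libsize_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sample_sheet(replicates: int) -> pd.DataFrame:
    rows = []
    for time in ("AM", "PM"):
        for condition in ("control", "heat"):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": f"{time}_{condition}_r{rep}",
                        "time": time,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with var = mu + alpha mu^2; alpha ~ 0 degenerates to Poisson."""
    counts = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        counts[nb] = rng.negative_binomial(size, p)
    return counts


def _truth_frame(
    rng: np.random.Generator, config: SimulationConfig
) -> pd.DataFrame:
    labels = sorted(config.archetype_proportions)
    probs = np.array([config.archetype_proportions[k] for k in labels])
    # deterministic rounded allocation keeps exact proportions at small n
    n_each = np.floor(probs * config.n_genes).astype(int)
    short = config.n_genes - n_each.sum()
    if short:
        order = np.argsort(-(probs * config.n_genes - n_each))
        n_each[order[:short]] += 1
    archetypes = np.repeat(labels, n_each)
    rng.shuffle(archetypes)

    mu0, sd0 = config.baseline_log_mean
    mua, sda = config.dispersion_log_mean
    baseline = np.exp(rng.normal(mu0, sd0, config.n_genes))
    alpha = np.exp(rng.normal(mua, sda, config.n_genes))

    signs = np.array([ARCHETYPE_SIGNS[a] for a in archetypes], dtype=float)
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "basal_log2fc": signs[:, 0] * config.basal_log2fc,
            "heat_am_log2fc": signs[:, 1] * config.heat_log2fc,
            "heat_pm_log2fc": signs[:, 2] * config.heat_log2fc,
            "baseline_mean": baseline,
            "dispersion": alpha,
        },
        index=pd.Index([f"gene{i:05d}" for i in range(config.n_genes)], name="gene"),
    )
    return truth


def _expected_means(truth: pd.DataFrame, samples: pd.DataFrame) -> np.ndarray:
    """Gene x sample expected means before library-size scaling.

    Baseline is the PM control mean; the basal effect applies to AM samples,
    heat effects to the heat samples of the matching time.
    """
    is_am = (samples["time"] == "AM").to_numpy(dtype=float)
    is_heat = (samples["condition"] == "heat").to_numpy(dtype=float)
    log2_mu = (
        truth["basal_log2fc"].to_numpy()[:, None] * is_am[None, :]
        + truth["heat_am_log2fc"].to_numpy()[:, None] * (is_am * is_heat)[None, :]
        + truth["heat_pm_log2fc"].to_numpy()[:, None] * ((1 - is_am) * is_heat)[None, :]
    )
    return truth["baseline_mean"].to_numpy()[:, None] * np.exp2(log2_mu)


def simulate_experiment(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a replicated 4-group experiment; returns (counts, truth table).

    Counts are NB with mean ``libsize_factor * baseline * 2**(basal*1[AM] +
    heatAM*1[AM,heat] + heatPM*1[PM,heat])`` and per-gene dispersion.  The
    same seed always yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_frame(rng, config)
    samples = _sample_sheet(config.replicates)
    mu = _expected_means(truth, samples)
    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    alpha = np.broadcast_to(
        truth["dispersion"].to_numpy()[:, None], mu.shape
    )
    counts = _nb_draw(rng, mu * libsize[None, :], np.ascontiguousarray(alpha))
    cm = CountMatrix(
        pd.DataFrame(counts, index=truth.index, columns=samples.index), samples
    )
    return cm, truth


def simulate_circadian_replicate(
    truth: pd.DataFrame,
    conserve_flags: pd.Series | np.ndarray,
    config: SimulationConfig,
) -> CountMatrix:
    """Simulate the constant-light follow-up: one replicate per group.

    Genes flagged conserved keep their diel effect pattern; for the rest the
    time-specific heat effects are replaced by a both-time response of the
    averaged magnitude, removing the gating while preserving the overall
    heat responsiveness.
    """
    flags = np.asarray(conserve_flags, dtype=bool)
    if flags.shape[0] != len(truth):
        raise ValidationError(
            f"conserve_flags length {flags.shape[0]} != {len(truth)} genes"
        )
    mod = truth.copy()
    avg = (mod["heat_am_log2fc"] + mod["heat_pm_log2fc"]) / 2.0
    mod.loc[~flags, "heat_am_log2fc"] = avg[~flags]
    mod.loc[~flags, "heat_pm_log2fc"] = avg[~flags]

    rng = np.random.default_rng(config.seed + 1)
    samples = _sample_sheet(1)
    mu = _expected_means(mod, samples)
    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    alpha = np.broadcast_to(mod["dispersion"].to_numpy()[:, None], mu.shape)
    counts = _nb_draw(rng, mu * libsize[None, :], np.ascontiguousarray(alpha))
    return CountMatrix(
        pd.DataFrame(counts, index=mod.index, columns=samples.index), samples
    )


def truth_category(truth_row) -> object:
    """Map a truth-table row to its refined-category number (1-18), the
    string flag ``discordant``, or ``None`` for null genes."""
    from .categorize import category_number

    am, pm = truth_row["heat_am_log2fc"], truth_row["heat_pm_log2fc"]
    if am == 0 and pm == 0:
        return None
    if am != 0 and pm != 0 and np.sign(am) != np.sign(pm):
        return "discordant"
    basal = truth_row["basal_log2fc"]
    basal_branch = "AM_higher" if basal > 0 else "PM_higher" if basal < 0 else "equal"
    timing = "both" if am != 0 and pm != 0 else "AM_only" if am != 0 else "PM_only"
    direction = "up" if (am or pm) > 0 else "down"
    return category_number(basal_branch, timing, direction)
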