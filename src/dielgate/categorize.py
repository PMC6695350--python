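"""Standard and refined categorization of time-of-day heat responses.

The *standard* categorization runs the per-time analyses independently and
summarises the up- and down-regulated calls in Venn regions (AM-only,
PM-only, both).

The *refined* categorization assigns every heat-responsive gene to one of
eighteen categories defined by three binary/ternary branches:

* basal branch — is unstressed expression higher in the AM, higher in the
  PM, or equal (from the AM control vs PM control contrast)?
* timing branch — does the gene respond to heat only in the AM, only in
  the PM, or at both times?
* direction — is the response up or down?

Category numbers follow a fixed grid: basal AM-higher covers 1-6,
PM-higher 7-12, equal 13-18; within each block AM-only responders take the
first pair, PM-only the second, both-times the third; odd numbers are
up-regulated, even numbers down-regulated.  A gene significant in both
heat contrasts with opposite signs fits none of the 18 patterns and is
flagged ``discordant``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Thresholds, ValidationError
from .de import DEResult

BASAL_BRANCHES = ("AM_higher", "PM_higher", "equal")
TIMING_BRANCHES = ("AM_only", "PM_only", "both")
DIRECTIONS = ("up", "down")

_BASAL_OFFSET = {"AM_higher": 0, "PM_higher": 6, "equal": 12}
_TIMING_OFFSET = {"AM_only": 0, "PM_only": 2, "both": 4}

#: named unions of categories used in reporting
CATEGORY_UNIONS: dict[str, tuple[int, ...]] = {
    "basal_am_higher": (1, 2, 3, 4, 5, 6),
    "basal_pm_higher": (7, 8, 9, 10, 11, 12),
    "basal_equal": (13, 14, 15, 16, 17, 18),
    "gated": (1, 2, 3, 4, 7, 8, 9, 10, 13, 14, 15, 16),
    "time_independent": (5, 6, 11, 12, 17, 18),
    "time_independent_equal_basal": (17, 18),
    "time_independent_basal_diff": (5, 6, 11, 12),
    "gated_equal_basal": (13, 14, 15, 16),
    "gated_equal_basal_am_only": (13, 14),
    "gated_equal_basal_pm_only": (15, 16),
    "gated_basal_diff": (1, 2, 3, 4, 7, 8, 9, 10),
    "gated_basal_diff_am_only": (1, 2, 7, 8),
    "gated_basal_diff_pm_only": (3, 4, 9, 10),
    "basal_driven_gated": (2, 3, 7, 10),
}


def category_number(basal: str, timing: str, direction: str) -> int:
    """The 1-18 category number for a (basal, timing, direction) triple."""
    if basal not in _BASAL_OFFSET or timing not in _TIMING_OFFSET or direction not in DIRECTIONS:
        raise ValidationError(f"invalid branch triple: {(basal, timing, direction)}")
    return _BASAL_OFFSET[basal] + _TIMING_OFFSET[timing] + (1 if direction == "up" else 2)


def category_branches(number: int) -> tuple[str, str, str]:
    """Inverse of :func:`category_number`."""
    if not 1 <= number <= 18:
        raise ValidationError(f"category number out of range: {number}")
    n = number - 1
    basal = BASAL_BRANCHES[n // 6]
    timing = TIMING_BRANCHES[(n % 6) // 2]
    direction = DIRECTIONS[n % 2]
    return basal, timing, direction


# ---------------------------------------------------------------------------
# Standard categorization (per-time Venn bookkeeping)


@dataclass
class StandardCategorization:
    """Up/down DE gene sets per time and their Venn regions."""

    am_up: set = field(default_factory=set)
    am_down: set = field(default_factory=set)
    pm_up: set = field(default_factory=set)
    pm_down: set = field(default_factory=set)

    @property
    def venn_up(self) -> dict[str, set]:
        return {
            "AM_only": self.am_up - self.pm_up,
            "PM_only": self.pm_up - self.am_up,
            "both": self.am_up & self.pm_up,
        }

    @property
    def venn_down(self) -> dict[str, set]:
        return {
            "AM_only": self.am_down - self.pm_down,
            "PM_only": self.pm_down - self.am_down,
            "both": self.am_down & self.pm_down,
        }

    @property
    def responsive(self) -> set:
        return self.am_up | self.am_down | self.pm_up | self.pm_down

    def totals(self) -> dict[str, int]:
        up = self.am_up | self.pm_up
        down = self.am_down | self.pm_down
        return {
            "responsive": len(self.responsive),
            "up": len(up),
            "down": len(down),
            **{f"up_{k}": len(v) for k, v in self.venn_up.items()},
            **{f"down_{k}": len(v) for k, v in self.venn_down.items()},
        }


def standard_categorize(
    de_am: DEResult, de_pm: DEResult, thresholds: Thresholds | None = None
) -> StandardCategorization:
    """Dual-threshold DE membership per time plus Venn set algebra.

    Both results must cover the same gene universe (the per-time analyses
    are run on the same filtered matrix).
    """
    thresholds = thresholds or Thresholds()
    if not de_am.genes.equals(de_pm.genes):
        raise ValidationError("AM and PM results cover different gene universes")
    sig_am = de_am.significant(thresholds)
    sig_pm = de_pm.significant(thresholds)
    up_am = sig_am & (de_am.table["log2FC"] > 0)
    dn_am = sig_am & (de_am.table["log2FC"] < 0)
    up_pm = sig_pm & (de_pm.table["log2FC"] > 0)
    dn_pm = sig_pm & (de_pm.table["log2FC"] < 0)
    return StandardCategorization(
        am_up=set(de_am.genes[up_am]),
        am_down=set(de_am.genes[dn_am]),
        pm_up=set(de_pm.genes[up_pm]),
        pm_down=set(de_pm.genes[dn_pm]),
    )


# ---------------------------------------------------------------------------
# Refined categorization


def refined_categorize(
    de2: dict[str, DEResult],
    thresholds: Thresholds | None = None,
    basal_requires_padj: bool = False,
) -> pd.DataFrame:
    """Assign refined categories from the three four-group-model contrasts.

    ``de2`` must contain ``AMheat_vs_AMctrl``, ``PMheat_vs_PMctrl`` and
    ``AMctrl_vs_PMctrl``.  A gene is heat-responsive iff significant
    (dual threshold) in at least one heat contrast.  The basal branch
    applies the fold-change criterion to the control-vs-control contrast;
    by default significance is not additionally required there
    (``basal_requires_padj`` enables the stricter variant).

    Returns a per-gene frame with columns ``category`` (nullable integer),
    ``basal``, ``timing``, ``direction`` and ``flag`` (``ok``,
    ``not_responsive`` or ``discordant``).
    """
    thresholds = thresholds or Thresholds()
    required = ("AMheat_vs_AMctrl", "PMheat_vs_PMctrl", "AMctrl_vs_PMctrl")
    missing = [k for k in required if k not in de2]
    if missing:
        raise ValidationError(f"missing contrast(s): {missing}")
    am, pm, basal = (de2[k] for k in required)
    genes = am.genes
    if not (genes.equals(pm.genes) and genes.equals(basal.genes)):
        raise ValidationError("contrasts cover different gene universes")

    sig_am = am.significant(thresholds).to_numpy()
    sig_pm = pm.significant(thresholds).to_numpy()
    lfc_am = am.table["log2FC"].to_numpy()
    lfc_pm = pm.table["log2FC"].to_numpy()
    lfc_basal = basal.table["log2FC"].to_numpy()
    if basal_requires_padj:
        basal_called = (basal.table["padj"] < thresholds.padj_cut).to_numpy()
    else:
        basal_called = np.ones(len(genes), dtype=bool)

    n = len(genes)
    category = np.full(n, np.nan)
    basal_branch = np.full(n, "", dtype=object)
    timing = np.full(n, "", dtype=object)
    direction = np.full(n, "", dtype=object)
    flag = np.full(n, "not_responsive", dtype=object)

    responsive = sig_am | sig_pm
    both = sig_am & sig_pm
    discordant = both & (np.sign(lfc_am) != np.sign(lfc_pm))
    flag[discordant] = "discordant"

    ok = responsive & ~discordant
    flag[ok] = "ok"
    basal_branch[ok] = np.where(
        basal_called[ok] & (lfc_basal[ok] > thresholds.lfc_cut),
        "AM_higher",
        np.where(
            basal_called[ok] & (lfc_basal[ok] < -thresholds.lfc_cut),
            "PM_higher",
            "equal",
        ),
    )
    timing[ok] = np.where(
        both[ok], "both", np.where(sig_am[ok], "AM_only", "PM_only")
    )
    # direction from the sign of the significant heat effect(s); for
    # both-times genes the two signs agree (discordant excluded above)
    sign = np.where(sig_am, np.sign(lfc_am), np.sign(lfc_pm))
    direction[ok] = np.where(sign[ok] > 0, "up", "down")
    for i in np.flatnonzero(ok):
        category[i] = category_number(basal_branch[i], timing[i], direction[i])

    return pd.DataFrame(
        {
            "category": pd.array(category, dtype="Int64"),
            "basal": basal_branch,
            "timing": timing,
            "direction": direction,
            "flag": flag,
        },
        index=genes,
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class CategorySummary:
    """Counts and nearest-integer percentages per category and union."""

    total_categorized: int
    per_category: pd.DataFrame  # index category 1..18: count, pct, reported
    unions: pd.DataFrame  # index union name: count, pct
    n_discordant: int = 0
    n_not_responsive: int = 0


def summarize_categories(
    rc: pd.DataFrame | dict[int, int], thresholds: Thresholds | None = None
) -> CategorySummary:
    """Bookkeeping over a refined categorization.

    Accepts either the per-gene frame from :func:`refined_categorize` or a
    plain ``{category: count}`` mapping.  Percentages are relative to the
    categorized (category 1-18) total, rounded to the nearest integer with
    half away from zero.  Categories smaller than ``category_min_size``
    keep their counts but are marked unreported.
    """
    thresholds = thresholds or Thresholds()
    n_disc = n_nr = 0
    if isinstance(rc, pd.DataFrame):
        counts = {
            int(c): int(n)
            for c, n in rc["category"].value_counts(dropna=True).items()
        }
        n_disc = int((rc["flag"] == "discordant").sum())
        n_nr = int((rc["flag"] == "not_responsive").sum())
    else:
        counts = {int(c): int(n) for c, n in rc.items()}
        bad = [c for c in counts if not 1 <= c <= 18]
        if bad:
            raise ValidationError(f"category number(s) out of range: {bad}")
    full = {c: counts.get(c, 0) for c in range(1, 19)}
    total = sum(full.values())

    def pct(n: int) -> int:
        return _round_half_away(100.0 * n / total) if total else 0

    per_category = pd.DataFrame(
        {
            "count": list(full.values()),
            "pct": [pct(v) for v in full.values()],
            "reported": [v >= thresholds.category_min_size for v in full.values()],
        },
        index=pd.Index(list(full.keys()), name="category"),
    )
    unions = pd.DataFrame(
        {
            "count": [sum(full[c] for c in cats) for cats in CATEGORY_UNIONS.values()],
        },
        index=pd.Index(list(CATEGORY_UNIONS.keys()), name="union"),
    )
    unions["pct"] = [pct(v) for v in unions["count"]]
    unions["categories"] = [
        ",".join(map(str, cats)) for cats in CATEGORY_UNIONS.values()
    ]
    return CategorySummary(
        total_categorized=total,
        per_category=per_category,
        unions=unions,
        n_discordant=n_disc,
        n_not_responsive=n_nr,
    )
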