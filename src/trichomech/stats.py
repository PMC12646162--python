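"""Group-level statistics of rupture measurements.

Rupture forces (and derived torques and critical stresses) are compared
across a two-factor design: tomato species (cultivar vs wild accession) ×
trichome location (leaf vs stem).  The analysis chain is the standard one
for such designs: 1.5·IQR outlier screening, per-group summaries, two-way
ANOVA (Type II sums of squares — the group sizes are unbalanced), and a
post-hoc Tukey HSD with a compact letter display, by default at the α = 0.02
significance threshold used for the letter annotations.

ANOVA and Tukey go through statsmodels; the IQR rule and the letter display
are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupedMeasurements",
    "iqr_outliers",
    "group_summary",
    "two_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "analyze_groups",
]

#: letter-display significance threshold for the group annotations
DEFAULT_ALPHA = 0.02


@dataclass
class GroupedMeasurements:
    """Long-format measurements with species/location factors.

    ``data`` columns: species, location, value (μN, μN·μm or MPa depending
    on the measure).  ``outlier_mask`` marks values flagged by the IQR rule.
    """

    data: pd.DataFrame
    measure: str = "F_r"
    units: str = "uN"
    outlier_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for col in ("species", "location", "value"):
            if col not in self.data.columns:
                raise ValueError(f"grouped data missing column {col!r}")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise ValueError("values must be finite")
        if self.outlier_mask is not None:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if len(self.outlier_mask) != len(self.data):
                raise ValueError("outlier mask length must equal data length")

    def clean(self) -> pd.DataFrame:
        """Rows surviving outlier removal (all rows if no mask set)."""
        if self.outlier_mask is None:
            return self.data
        return self.data.loc[~self.outlier_mask]

    def flag_outliers(self, per_group: bool = False) -> "GroupedMeasurements":
        """Apply the 1.5·IQR rule, pooled over all values by default."""
        if per_group:
            mask = np.zeros(len(self.data), dtype=bool)
            for _, idx in self.data.groupby(["species", "location"]).groups.items():
                mask[self.data.index.get_indexer(idx)] = iqr_outliers(
                    self.data.loc[idx, "value"].to_numpy())
        else:
            mask = iqr_outliers(self.data["value"].to_numpy())
        self.outlier_mask = mask
        return self


def iqr_outliers(values, factor: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation between order statistics (numpy's
    default convention).  Fewer than 4 values cannot define meaningful
    quartile fences; a warning is emitted and nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values: IQR outlier rule not applied",
                      stacklevel=2)
        return np.zeros(len(values), dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return (values < lo) | (values > hi)


def group_summary(grouped: GroupedMeasurements) -> pd.DataFrame:
    """Per-group mean, SD and n after outlier removal."""
    df = grouped.clean()
    if df.empty:
        raise ValueError("no measurements left after outlier removal")
    out = (df.groupby(["species", "location"])["value"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
             .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    out["units"] = grouped.units
    out["measure"] = grouped.measure
    return out


def two_way_anova(grouped: GroupedMeasurements, typ: int = 2) -> pd.DataFrame:
    """Two-way ANOVA with interaction on species × location.

    Type II sums of squares by default — appropriate for testing main
    effects in the unbalanced design; Type I/III available via ``typ``.
    """
    df = grouped.clean()
    counts = df.groupby(["species", "location"]).size()
    for sp in df["species"].unique():
        for loc in df["location"].unique():
            if (sp, loc) not in counts.index or counts[(sp, loc)] < 2:
                raise ValueError(
                    f"cell (species={sp!r}, location={loc!r}) has fewer than "
                    "2 observations; the two-way model is not estimable")
    if df["species"].nunique() < 2 or df["location"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    model = smf.ols("value ~ C(species) * C(location)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    table = table.rename(index={
        "C(species)": "species", "C(location)": "location",
        "C(species):C(location)": "species:location", "Residual": "residual"})
    return table


def tukey_hsd(grouped: GroupedMeasurements, alpha: float = DEFAULT_ALPHA):
    """All-pairs Tukey HSD over the species×location groups.

    Groups with a single observation are excluded (with a warning): they
    contribute no within-group variance.  Returns (pairwise DataFrame with
    studentized-range adjusted p-values, letters dict).  Groups sharing a
    letter are not significantly different at ``alpha``.
    """
    df = grouped.clean().copy()
    df["group"] = df["species"].astype(str) + ":" + df["location"].astype(str)
    sizes = df.groupby("group").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups excluded from Tukey HSD (n=1): {singletons}",
                      stacklevel=2)
        df = df[~df["group"].isin(singletons)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups with n >= 2 for Tukey HSD")
    res = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(),
                            alpha=alpha)
    pairs = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    pairs["p_adj"] = np.asarray(res.pvalues, dtype=float)
    groups = list(res.groupsunique)
    sig = {}
    k = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalues[k])
            sig[(groups[i], groups[j])] = p < alpha
            sig[(groups[j], groups[i])] = p < alpha
            k += 1
    means = df.groupby("group")["value"].mean()
    letters = compact_letter_display(groups, sig, order=means)
    return pairs, letters


def compact_letter_display(groups, significant: dict, order=None) -> dict:
    """Assign letters so that groups sharing a letter are not significantly
    different (insert-and-absorb algorithm).

    ``significant[(a, b)]`` is True when a and b differ significantly.
    ``order`` optionally maps group -> sort key (e.g. group means, so 'a'
    goes to the largest group, the usual display convention).
    """
    if order is not None:
        groups = sorted(groups, key=lambda g: -float(order[g]))
    # letter sets: each is the set of groups sharing one letter
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(not significant.get((g, other), False) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop letter sets fully contained in another
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(i != j and s < t for j, t in enumerate(letter_sets))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def analyze_groups(data: pd.DataFrame, *, measure: str = "F_r", units: str = "uN",
                   alpha: float = DEFAULT_ALPHA, per_group_outliers: bool = False):
    """Full chain: IQR screen → summary → ANOVA → Tukey letters."""
    gm = GroupedMeasurements(data, measure=measure, units=units)
    gm.flag_outliers(per_group=per_group_outliers)
    summary = group_summary(gm)
    anova = two_way_anova(gm)
    pairs, letters = tukey_hsd(gm, alpha=alpha)
    return {
        "grouped": gm,
        "n_outliers": int(gm.outlier_mask.sum()),
        "summary": summary,
        "anova": anova,
        "tukey": pairs,
        "letters": letters,
    }
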