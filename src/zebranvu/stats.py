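"""Group comparison for the 2x2 osmolyte x SNP design.

Per endpoint: Shapiro-Wilk normality per design cell (reported, never acted
on), two-way ANOVA (type-II sums of squares) with interaction, and Sidak-
adjusted pairwise cell comparisons (pooled-variance t-tests).  The default
comparison family is the four contrasts drawn in the study's figures:
mannitol vs glucose, glucose vs glucose+SNP, mannitol vs mannitol+SNP, and
mannitol vs glucose+SNP; the fully crossed six-pair family is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "DEFAULT_PAIRS",
    "ALL_PAIRS",
    "GroupStatsResult",
    "normality_check",
    "two_way_anova_sidak",
    "summarize",
    "significance_stars",
]

CELLS = (
    ("mannitol", False),
    ("mannitol", True),
    ("glucose", False),
    ("glucose", True),
)


def _cell_label(osmolyte: str, snp: bool) -> str:
    return f"{osmolyte}+SNP" if snp else osmolyte


DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("mannitol", "glucose"),
    ("glucose", "glucose+SNP"),
    ("mannitol", "mannitol+SNP"),
    ("mannitol", "glucose+SNP"),
)
ALL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (_cell_label(*CELLS[i]), _cell_label(*CELLS[j]))
    for i in range(4)
    for j in range(i + 1, 4)
)


@dataclass
class GroupStatsResult:
    """Statistics for one endpoint."""

    endpoint: str
    shapiro_p: dict[str, float]
    normality_warning: bool
    anova: pd.DataFrame  # rows: osmolyte, snp, interaction, residual
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_sidak, significant
    alpha: float = 0.05

    @property
    def anova_p(self) -> dict[str, float]:
        return {k: float(self.anova.loc[k, "PR(>F)"]) for k in ("osmolyte", "snp", "interaction")}


def normality_check(table: pd.DataFrame, endpoint: str, value_col: str = "value") -> dict[str, float]:
    """Shapiro-Wilk p per design cell for one endpoint.

    Requires n >= 3 non-constant observations per occupied cell.
    """
    sub = table[table["endpoint"] == endpoint] if "endpoint" in table.columns else table
    out: dict[str, float] = {}
    for osmolyte, snp in CELLS:
        vals = sub[(sub["osmolyte"] == osmolyte) & (sub["snp"] == snp)][value_col].to_numpy(float)
        if len(vals) == 0:
            continue
        if len(vals) < 3:
            raise ValueError(f"cell {_cell_label(osmolyte, snp)}: need >= 3 values for Shapiro-Wilk")
        if np.ptp(vals) == 0:
            raise ValueError(f"cell {_cell_label(osmolyte, snp)}: constant values")
        out[_cell_label(osmolyte, snp)] = float(sps.shapiro(vals).pvalue)
    return out


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak familywise adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    return 1.0 - (1.0 - p) ** m


def two_way_anova_sidak(
    table: pd.DataFrame,
    endpoint: str,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    alpha: float = 0.05,
    value_col: str = "value",
) -> GroupStatsResult:
    """Two-way ANOVA (osmolyte x SNP, type-II SS) with Sidak post-hoc pairs.

    ``table`` is tidy: columns ``larva_id``, ``osmolyte``, ``snp``,
    ``endpoint``, ``value`` (or pass a single-endpoint table without the
    endpoint column).  Every design cell must contain >= 2 observations.
    """
    sub = table[table["endpoint"] == endpoint] if "endpoint" in table.columns else table
    sub = sub.dropna(subset=[value_col]).copy()
    if not np.all(np.isfinite(sub[value_col].to_numpy(float))):
        raise ValueError("endpoint values must be finite")
    for osmolyte, snp in CELLS:
        n = ((sub["osmolyte"] == osmolyte) & (sub["snp"] == snp)).sum()
        if n < 2:
            raise ValueError(
                f"cell {_cell_label(osmolyte, snp)} has {n} observation(s); need >= 2"
            )
    shapiro_p = normality_check(sub, endpoint, value_col=value_col)
    normality_warning = any(p < alpha for p in shapiro_p.values())
    if normality_warning:
        warnings.warn(
            f"{endpoint}: Shapiro-Wilk p < {alpha} in at least one cell; "
            "ANOVA assumptions may be violated",
            stacklevel=2,
        )

    df = sub.rename(columns={value_col: "value"})
    df["snp"] = df["snp"].astype(bool)
    model = smf.ols("value ~ C(osmolyte) * C(snp)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(osmolyte)": "osmolyte",
            "C(snp)": "snp",
            "C(osmolyte):C(snp)": "interaction",
            "Residual": "residual",
        }
    )

    groups = {
        _cell_label(o, s): df[(df["osmolyte"] == o) & (df["snp"] == s)]["value"].to_numpy(float)
        for o, s in CELLS
    }
    rows = []
    for ga, gb in pairs:
        t, p = sps.ttest_ind(groups[ga], groups[gb], equal_var=True)
        rows.append({"group_a": ga, "group_b": gb, "t": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_sidak"] = sidak_adjust(pairwise["p_raw"].to_numpy(), m=len(pairs))
    pairwise["significant"] = pairwise["p_sidak"] < alpha

    return GroupStatsResult(
        endpoint=endpoint,
        shapiro_p=shapiro_p,
        normality_warning=normality_warning,
        anova=aov,
        pairwise=pairwise,
        alpha=alpha,
    )


def significance_stars(p: float) -> str:
    """Figure-legend asterisk bands: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(results: list[GroupStatsResult]) -> pd.DataFrame:
    """Tidy report: one row per endpoint x (ANOVA term | pairwise contrast)."""
    rows = []
    for res in results:
        for term in ("osmolyte", "snp", "interaction"):
            p = float(res.anova.loc[term, "PR(>F)"])
            rows.append(
                {
                    "endpoint": res.endpoint,
                    "test": f"anova:{term}",
                    "statistic": float(res.anova.loc[term, "F"]),
                    "p": p,
                    "p_adjusted": p,
                    "stars": significance_stars(p),
                    "normality_warning": res.normality_warning,
                }
            )
        for _, row in res.pairwise.iterrows():
            rows.append(
                {
                    "endpoint": res.endpoint,
                    "test": f"{row['group_a']} vs {row['group_b']}",
                    "statistic": row["t"],
                    "p": row["p_raw"],
                    "p_adjusted": row["p_sidak"],
                    "stars": significance_stars(row["p_sidak"]),
                    "normality_warning": res.normality_warning,
                }
            )
    return pd.DataFrame(rows)
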