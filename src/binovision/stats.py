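"""Group-level statistical battery for the binocular-function measures.

Between-group comparisons use two-sided Mann–Whitney U tests reported with
the tie-corrected normal-approximation Z; correlations are Spearman rank
correlations, compared across groups with the Fisher r-to-z transformation
applied directly to rho with standard error sqrt(1/(n-3)); the three
stereoacuity test methods are compared with a fully between-subjects
2x3 ANOVA (group x test) with Bonferroni-corrected pairwise post hocs; and
a priori power for the Wilcoxon–Mann–Whitney test is computed by the
asymptotic-relative-efficiency method (normal parents, ARE = 0.955) with
the noncentral t distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatTestResult",
    "SpearmanResult",
    "AnovaTable",
    "mann_whitney",
    "spearman",
    "fisher_compare",
    "two_way_anova",
    "two_way_anova_from_summary",
    "wmw_power",
]


@dataclass(frozen=True)
class StatTestResult:
    name: str
    statistic: float
    z: float
    p: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"test": self.name, "statistic": self.statistic, "z": self.z,
                "p": self.p, "n1": self.n1, "n2": self.n2}


def mann_whitney(x, y, name: str = "mann-whitney") -> StatTestResult:
    """Two-sided Mann–Whitney U test with tie-corrected normal Z.

    The U statistic is for the first sample; Z is signed so that a first
    sample with larger values gives a positive Z (no continuity
    correction, matching a large-sample rank-test report).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (u1 - mu) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return StatTestResult(name=name, statistic=float(u1), z=float(z), p=float(p),
                          n1=n1, n2=n2)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.rho)


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with midrank ties and a t-approximation p.

    A constant input leaves the correlation undefined; the result carries
    NaN and ``defined`` is False rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=math.nan, p=math.nan, n=len(x))
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p=float(p), n=len(x))


def fisher_compare(rho1: float, n1: int, rho2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via the Fisher r-to-z transform.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    for rho in (rho1, rho2):
        if not abs(rho) < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    z = (math.atanh(rho1) - math.atanh(rho2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return z, p


@dataclass(frozen=True)
class AnovaTable:
    """Two-way between-subjects ANOVA with Bonferroni post hocs.

    ``effects`` maps effect name (group, test, interaction, error) to a dict
    with df, sum_sq, F, p; ``posthoc`` lists Bonferroni-adjusted pairwise
    comparisons among the test methods using the pooled error term.
    """

    effects: dict
    posthoc: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"effects": self.effects, "posthoc": self.posthoc}


def two_way_anova(values, factor_group, factor_test) -> AnovaTable:
    """Fully between-subjects two-way ANOVA (group x test) with interaction.

    Sums of squares are Type II (equivalent to the classical decomposition
    in the balanced case); pairwise post hocs among test levels use the
    pooled error mean square with Bonferroni correction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "grp": np.asarray(factor_group, dtype=object),
        "tst": np.asarray(factor_test, dtype=object),
    })
    if df["grp"].nunique() < 2 or df["tst"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    model = smf.ols("value ~ C(grp) * C(tst)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss_total = float(((df["value"] - df["value"].mean()) ** 2).sum())
    degenerate = ss_total <= 1e-12 * max(1.0, float(np.abs(df["value"]).max()) ** 2)
    effects = {}
    for row, key in (("C(grp)", "group"), ("C(tst)", "test"),
                     ("C(grp):C(tst)", "interaction"), ("Residual", "error")):
        r = tab.loc[row]
        effects[key] = {
            "df": float(r["df"]),
            "sum_sq": 0.0 if degenerate else float(r["sum_sq"]),
            "F": None if key == "error" else (0.0 if degenerate else float(r["F"])),
            "p": None if key == "error" else (1.0 if degenerate else float(r["PR(>F)"])),
        }
    mse = effects["error"]["sum_sq"] / effects["error"]["df"]
    dfe = effects["error"]["df"]
    levels = sorted(df["tst"].unique())
    n_comp = len(levels) * (len(levels) - 1) // 2
    posthoc = []
    for a, b in itertools.combinations(levels, 2):
        va = df.loc[df["tst"] == a, "value"]
        vb = df.loc[df["tst"] == b, "value"]
        if mse <= 0:
            t, p = 0.0, 1.0
        else:
            t = (va.mean() - vb.mean()) / math.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            p = min(1.0, n_comp * 2.0 * sps.t.sf(abs(t), dfe))
        posthoc.append({"pair": (a, b), "t": float(t), "p_bonferroni": float(p)})
    return AnovaTable(effects=effects, posthoc=posthoc)


def two_way_anova_from_summary(cells: dict) -> AnovaTable:
    """ANOVA from per-cell summary statistics.

    ``cells`` maps (group, test) -> (mean, sd, n).  A between-subjects
    ANOVA depends on the data only through these summaries, so an exact
    surrogate sample is reconstructed per cell (affinely standardised to
    the given mean and sd) and passed through the data-variant ANOVA.
    """
    values, grp, tst = [], [], []
    for (g, t), (mean, sd, n) in cells.items():
        if n < 2:
            raise ValueError("each cell needs n >= 2")
        base = np.linspace(-1.0, 1.0, int(n))
        base = (base - base.mean()) / base.std(ddof=1)
        values.extend(mean + sd * base)
        grp.extend([g] * int(n))
        tst.extend([t] * int(n))
    return two_way_anova(values, grp, tst)


def wmw_power(
    mean1: float, sd1: float, mean2: float, sd2: float,
    n_per_group: int, alpha: float = 0.05, are: float = 0.955,
) -> float:
    """A priori power of the two-sided Wilcoxon–Mann–Whitney test.

    Uses the asymptotic-relative-efficiency method with normal parent
    distributions: the t-test power formula evaluated at an effective
    per-group sample size ``are * n`` with effect size
    d = |mean1 - mean2| / sqrt((sd1^2 + sd2^2)/2) and the noncentral t
    distribution.  Equal means return exactly ``alpha``.
    """
    if not (sd1 > 0 and sd2 > 0):
        raise ValueError("standard deviations must be positive")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    d = abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)
    ne = are * n_per_group
    dof = 2.0 * ne - 2.0
    ncp = d * math.sqrt(ne / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, dof)
    power = sps.nct.sf(tcrit, dof, ncp) + sps.nct.cdf(-tcrit, dof, ncp)
    return float(power)
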