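"""West/East two-group statistical comparison: normality gating, two-tailed
Mann–Whitney U, descriptive tables and whistle-type proportions.

Normality is assessed with Shapiro–Wilk for n ≤ 50 and one-sample
Kolmogorov–Smirnov against a normal with the sample's mean and SD for
n > 50; group differences use the two-tailed Mann–Whitney U test at
α = 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSamples",
    "TestResult",
    "normality_gate",
    "mann_whitney_u",
    "exact_mwu_pvalue",
    "describe",
    "type_proportions",
    "compare_report",
    "load_vessel_csv",
]

ALPHA = 0.05
#: exact enumeration only when the labeling count is tractable
MAX_EXACT_COMBINATIONS = 500_000


@dataclass
class GroupedSamples:
    parameter: str
    west: np.ndarray
    east: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.west = np.asarray(self.west, dtype=np.float64)
        self.east = np.asarray(self.east, dtype=np.float64)
        for name, values in (("west", self.west), ("east", self.east)):
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite values in {name} group of {self.parameter}")


@dataclass
class TestResult:
    test: str
    statistic: float  # U for the west group
    p_value: float
    n_west: int
    n_east: int
    normality: Dict[str, Tuple[str, float, float]] = field(default_factory=dict)
    degenerate: bool = False
    #: U convention: statistic is U for the first (west) group;
    #: U_east = n_west*n_east − U_west.
    convention: str = "U_west"


def normality_gate(values: Sequence[float]) -> Tuple[str, float, float]:
    """(decision, statistic, p): Shapiro–Wilk for n ≤ 50, one-sample KS
    against N(mean, sd) for n > 50; non-normal iff p < 0.05."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("normality assessment needs n >= 3")
    if x.size <= 50:
        stat, p = sps.shapiro(x)
        test = "shapiro-wilk"
    else:
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        test = "kolmogorov-smirnov"
    return ("non-normal" if p < ALPHA else "normal", float(stat), float(p))


def exact_mwu_pvalue(west: np.ndarray, east: np.ndarray) -> Tuple[float, float]:
    """(U_west, exact two-tailed p) by enumerating every labeling of the
    pooled sample; ties handled with midranks.  Two-tailed p is
    2·min(P(U ≤ u), P(U ≥ u)) capped at 1."""
    n1, n2 = len(west), len(east)
    pooled = np.concatenate([west, east])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = comb(n1 + n2, n1)
    le = ge = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(u_obs), float(p)


def mann_whitney_u(west: Sequence[float], east: Sequence[float]) -> TestResult:
    """Two-tailed Mann–Whitney U.  Exact enumeration when min(n) ≤ 8 (and the
    labeling count is tractable), tie-corrected normal approximation with
    continuity correction otherwise.  The reported statistic is U for the
    west group."""
    w = np.asarray(west, dtype=np.float64)
    e = np.asarray(east, dtype=np.float64)
    if w.size == 0 or e.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([w, e])) == 0.0:
        u = w.size * e.size / 2.0
        return TestResult("mann-whitney-u", u, 1.0, w.size, e.size, degenerate=True)
    if min(w.size, e.size) <= 8 and comb(w.size + e.size, min(w.size, e.size)) <= MAX_EXACT_COMBINATIONS:
        u, p = exact_mwu_pvalue(w, e)
        test = "mann-whitney-u-exact"
    else:
        res = sps.mannwhitneyu(w, e, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney-u-asymptotic"
    return TestResult(test, u, p, w.size, e.size)


def describe(values: Sequence[float]) -> Tuple[float, float, float, float]:
    """(mean, SD with n−1 denominator, min, max); SD is 0 for n = 1."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 1:
        raise ValueError("describe needs n >= 1")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd, float(x.min()), float(x.max())


def type_proportions(labels: Sequence[str]) -> pd.DataFrame:
    """Count and percentage (2 decimals) per whistle shape type."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame({"count": counts, "percent": (100.0 * counts / len(labels)).round(2)})
    out.index.name = "type"
    return out


def compare_report(
    grouped: Sequence[GroupedSamples],
    alpha: float = ALPHA,
) -> Tuple[dict, str]:
    """Per-parameter report: normality decisions, test, U, p, group
    descriptives and a significance flag; returns (JSON-ready dict,
    Markdown table)."""
    if not grouped:
        raise ValueError("at least one parameter required")
    entries = []
    for g in grouped:
        result = mann_whitney_u(g.west, g.east)
        for name, values in (("west", g.west), ("east", g.east)):
            if values.size >= 3:
                result.normality[name] = normality_gate(values)
        mw, sw, lw, hw = describe(g.west)
        me, se, le, he = describe(g.east)
        entries.append(
            {
                "parameter": g.parameter,
                "units": g.units,
                "west": {"n": int(g.west.size), "mean": mw, "sd": sw, "min": lw, "max": hw},
                "east": {"n": int(g.east.size), "mean": me, "sd": se, "min": le, "max": he},
                "normality": {k: {"decision": v[0], "statistic": v[1], "p": v[2]}
                              for k, v in result.normality.items()},
                "test": result.test,
                "U": result.statistic,
                "U_convention": result.convention,
                "p": result.p_value,
                "significant": bool(result.p_value < alpha and not result.degenerate),
                "degenerate": result.degenerate,
            }
        )
    report = {"alpha": alpha, "correction": "none", "parameters": entries}
    lines = [
        "| parameter | west mean ± SD | east mean ± SD | U | p | significant |",
        "|---|---|---|---|---|---|",
    ]
    for e in entries:
        lines.append(
            f"| {e['parameter']} ({e['units']}) "
            f"| {e['west']['mean']:.1f} ± {e['west']['sd']:.1f} "
            f"| {e['east']['mean']:.1f} ± {e['east']['sd']:.1f} "
            f"| {e['U']:.6g} | {e['p']:.3g} | {'yes' if e['significant'] else 'no'} |"
        )
    return report, "\n".join(lines)


def load_vessel_csv(path) -> GroupedSamples:
    """Monthly vessel-density table (columns: month, region, density or
    hours_per_km2) → grouped samples with months as sampling units."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    value_col = next(c for c in df.columns if c not in ("month", "region"))
    region = df["region"].str.strip().str.lower()
    return GroupedSamples(
        parameter="vessel_density",
        west=df.loc[region == "west", value_col].to_numpy(),
        east=df.loc[region == "east", value_col].to_numpy(),
        units=value_col,
    )
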