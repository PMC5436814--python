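"""Observed-vs-expected abundance statistics for mock-community validation.

Observed percentages are read shares within a sample.  Quantitative
fidelity is scored by ordinary least squares of log10(observed %) on
log10(expected %), either across species within one community or across
communities within one species: a significant positive slope near 1 with
high R^2 means read abundance tracks input copy number.  Blocking-primer
efficacy is the relative reduction of the blocked taxon's read percentage
between paired runs with and without the blocking primer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def observed_percentages(counts: dict[str, int]) -> pd.DataFrame:
    """Per-species observed read percentages (exact, unrounded).

    Raises ``ValueError`` when all counts are zero.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all read counts are zero")
    return pd.DataFrame(
        {
            "species": list(counts),
            "read_count": list(counts.values()),
            "pct_observed": [100.0 * c / total for c in counts.values()],
        }
    )


def abundance_table(
    counts: dict[str, int], expected: dict[str, float]
) -> pd.DataFrame:
    """Join observed percentages with expected percentages."""
    df = observed_percentages(counts)
    df["pct_expected"] = [expected.get(s, 0.0) for s in df["species"]]
    return df


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    excluded_zero_count: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["slope", "intercept", "r_squared", "p_value", "n_points", "excluded_zeros"],
                "value": [self.slope, self.intercept, self.r_squared, self.p_value, self.n_points, self.excluded_zero_count],
            }
        )


def loglog_regression(
    points,
    zero_policy: str = "exclude",
    floor: float = 1e-4,
) -> RegressionResult:
    """OLS of log10(observed %) on log10(expected %).

    ``points`` is an iterable of ``(pct_expected, pct_observed)`` pairs (or
    a DataFrame with those columns).  Zero observed percentages are handled
    by ``zero_policy``: ``"exclude"`` drops the point (count reported) or
    ``"floor"`` replaces it with ``floor``.  Points with zero expected
    percentage are always excluded (a non-amplifiable species has no
    defined expectation on the log scale).  The p-value is the two-sided
    t-test of slope != 0.
    """
    if zero_policy not in ("exclude", "floor"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if isinstance(points, pd.DataFrame):
        pairs = list(zip(points["pct_expected"], points["pct_observed"]))
    else:
        pairs = list(points)
    xs, ys = [], []
    excluded = 0
    for exp_pct, obs_pct in pairs:
        if exp_pct <= 0:
            excluded += 1
            continue
        if obs_pct <= 0:
            if zero_policy == "exclude":
                excluded += 1
                continue
            obs_pct = floor
        xs.append(math.log10(exp_pct))
        ys.append(math.log10(obs_pct))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 usable points, got {len(xs)}")
    if len(set(xs)) < 2:
        raise ValueError("expected percentages are constant; slope undefined")
    fit = sps.linregress(np.asarray(xs), np.asarray(ys))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=len(xs),
        excluded_zero_count=excluded,
    )


def regressions_by_community(table: pd.DataFrame) -> pd.DataFrame:
    """Per-community OLS across species.  ``table`` needs columns
    community, species, pct_expected, pct_observed."""
    rows = []
    for cid, grp in table.groupby("community", sort=True):
        res = loglog_regression(grp)
        rows.append(dict(unit=str(cid), **res.__dict__))
    return pd.DataFrame(rows)


def regressions_by_species(table: pd.DataFrame) -> pd.DataFrame:
    """Per-species OLS across communities; species with undefined fits
    (constant expectation or too few nonzero points) are reported with NaN."""
    rows = []
    for sp, grp in table.groupby("species", sort=True):
        try:
            res = loglog_regression(grp)
            rows.append(dict(unit=sp, **res.__dict__))
        except ValueError:
            rows.append(
                dict(
                    unit=sp,
                    slope=float("nan"),
                    intercept=float("nan"),
                    r_squared=float("nan"),
                    p_value=float("nan"),
                    n_points=0,
                    excluded_zero_count=int((grp["pct_observed"] <= 0).sum()),
                )
            )
    return pd.DataFrame(rows)


def blocking_reduction(pct_with_block: float, pct_without_block: float) -> float | None:
    """Percent reduction of a taxon's read share due to the blocking primer.

    ``100 * (1 - with/without)``.  Negative values mean the share
    *increased*.  Undefined (returns ``None``) when the without-block share
    is zero — with zero baseline no reduction is measurable — including the
    both-zero case.
    """
    if pct_without_block < 0 or pct_with_block < 0:
        raise ValueError("percentages must be non-negative")
    if pct_without_block == 0:
        return None
    return 100.0 * (1.0 - pct_with_block / pct_without_block)


def blocking_reduction_table(comparison: pd.DataFrame, species: str) -> pd.DataFrame:
    """Blocking-primer reduction for one species across paired samples.

    ``comparison`` needs columns sample, species, reads_with_block,
    reads_without_block; percentages are recomputed within each sample
    before the reduction is taken.
    """
    rows = []
    for sample, grp in comparison.groupby("sample", sort=True):
        with_pct = 100.0 * grp["reads_with_block"] / grp["reads_with_block"].sum()
        without_pct = (
            100.0 * grp["reads_without_block"] / grp["reads_without_block"].sum()
        )
        mask = grp["species"] == species
        if not mask.any():
            continue
        w = float(with_pct[mask].iloc[0])
        wo = float(without_pct[mask].iloc[0])
        rows.append(
            dict(
                sample=sample,
                species=species,
                pct_with_block=w,
                pct_without_block=wo,
                reduction_pct=blocking_reduction(w, wo),
            )
        )
    return pd.DataFrame(rows)


def plot_loglog(table: pd.DataFrame, ax=None, label: str | None = None):
    """Convenience scatter of log10 observed vs expected with the OLS line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    usable = table[(table["pct_expected"] > 0) & (table["pct_observed"] > 0)]
    x = np.log10(usable["pct_expected"])
    y = np.log10(usable["pct_observed"])
    ax.scatter(x, y, label=label)
    res = loglog_regression(usable)
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, res.intercept + res.slope * xs)
    ax.set_xlabel("log10 expected read %")
    ax.set_ylabel("log10 observed read %")
    return ax
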