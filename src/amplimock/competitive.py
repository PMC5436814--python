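"""Competitive-PCR copy-number quantification and mock-community recipes.

A native template (NT, the DNA extraction) is co-amplified with a serial
dilution of an internal standard (IS): a synthetic homolog sharing both
primer sites but carrying an interior deletion so products separate by
size.  Because both templates compete for the same primers with equal
efficiency, the product ratio reflects the starting ratio.  Regressing

    log10(NT molarity / IS molarity)  on  log10(IS copies/reaction)

gives a line of ideal slope -1; its y-intercept locates the IS input at
which NT:IS = 1:1, so the NT concentration is ``10 ** intercept`` copies
per reaction.  The model object follows the usual construct-then-``fit``
pattern and returns a results object with estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iupac import SEQUENCE_ALPHABET


@dataclass(frozen=True)
class CompetitiveSeries:
    """One dilution series: (is_copies, nt_molarity, is_molarity) points."""

    points: pd.DataFrame
    extraction_id: str = ""

    @classmethod
    def from_records(cls, records, extraction_id: str = "") -> "CompetitiveSeries":
        df = pd.DataFrame(records, columns=["is_copies", "nt_molarity", "is_molarity"])
        return cls(df, extraction_id)


class CompetitivePcr:
    """Competitive-PCR model for one extraction's dilution series.

    Parameters
    ----------
    series
        A :class:`CompetitiveSeries` or a DataFrame with columns
        ``is_copies`` (copies/reaction, > 0), ``nt_molarity`` (>= 0) and
        ``is_molarity`` (> 0).  Points with ``nt_molarity == 0`` (NT fully
        out-competed) are excluded from the fit and counted.
    """

    def __init__(self, series, extraction_id: str = ""):
        if isinstance(series, CompetitiveSeries):
            df = series.points.copy()
            extraction_id = extraction_id or series.extraction_id
        else:
            df = pd.DataFrame(series).copy()
        required = {"is_copies", "nt_molarity", "is_molarity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"series missing columns: {sorted(missing)}")
        if (df["is_copies"] <= 0).any():
            raise ValueError("is_copies must be positive")
        if (df["is_molarity"] <= 0).any():
            raise ValueError("is_molarity must be positive")
        if (df["nt_molarity"] < 0).any():
            raise ValueError("nt_molarity must be non-negative")
        if df["is_copies"].nunique() < 2:
            raise ValueError("is_copies must vary across the dilution series")
        self.extraction_id = extraction_id
        self.data = df.reset_index(drop=True)

    def fit(self, slope_tolerance: float = 0.15) -> "CompetitivePcrResults":
        """OLS of log-ratio on log IS copies; NT copies = 10**intercept.

        ``slope_tolerance`` sets the warning band around the ideal slope of
        -1; a fitted slope outside it flags a series where the intercept
        rule is unreliable (e.g. unequal NT/IS amplification efficiency).
        """
        usable = self.data[self.data["nt_molarity"] > 0]
        excluded = len(self.data) - len(usable)
        if len(usable) < 3:
            raise ValueError(
                f"need >= 3 points with nt_molarity > 0, got {len(usable)}"
            )
        x = np.log10(usable["is_copies"].to_numpy(dtype=float))
        y = np.log10(
            usable["nt_molarity"].to_numpy(dtype=float)
            / usable["is_molarity"].to_numpy(dtype=float)
        )
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        if abs(slope) > 1e-12:
            nt_root = float(10.0 ** (-intercept / slope))
        else:
            nt_root = float("nan")
        return CompetitivePcrResults(
            model=self,
            nt_copies=float(10.0**intercept),
            nt_copies_root=nt_root,
            slope=slope,
            intercept=intercept,
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            stderr_slope=float(fit.stderr),
            n_points=len(usable),
            excluded_zero_count=excluded,
            slope_warning=abs(slope + 1.0) > slope_tolerance,
        )


@dataclass(frozen=True)
class CompetitivePcrResults:
    model: CompetitivePcr
    nt_copies: float
    nt_copies_root: float  # diagnostic alternative: 10**(-intercept/slope)
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr_slope: float
    n_points: int
    excluded_zero_count: int
    slope_warning: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "extraction_id",
                    "nt_copies (10^intercept)",
                    "nt_copies_root (10^(-b0/b1))",
                    "slope",
                    "intercept",
                    "r_squared",
                    "p_value",
                    "n_points",
                    "excluded_zero_points",
                    "slope_warning",
                ],
                "value": [
                    self.model.extraction_id,
                    self.nt_copies,
                    self.nt_copies_root,
                    self.slope,
                    self.intercept,
                    self.r_squared,
                    self.p_value,
                    self.n_points,
                    self.excluded_zero_count,
                    self.slope_warning,
                ],
            }
        )


def estimate_copy_number(series, **fit_kwargs) -> CompetitivePcrResults:
    """Convenience wrapper: ``CompetitivePcr(series).fit(**fit_kwargs)``."""
    return CompetitivePcr(series).fit(**fit_kwargs)


def simulate_series(
    nt_copies: float,
    is_copies: np.ndarray | list[float],
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    extraction_id: str = "sim",
) -> CompetitiveSeries:
    """Generate a dilution series with multiplicative lognormal noise.

    Under ideal competition the product molarity ratio equals the template
    copy ratio: ``nt_molarity / is_molarity = nt_copies / is_copies``.
    ``noise_sigma`` is the standard deviation of the natural-log
    measurement noise applied to the ratio.
    """
    rng = rng or np.random.default_rng()
    is_copies = np.asarray(is_copies, dtype=float)
    ratio = nt_copies / is_copies
    if noise_sigma > 0:
        ratio = ratio * rng.lognormal(mean=0.0, sigma=noise_sigma, size=ratio.shape)
    is_mol = np.full_like(is_copies, 1.0)
    return CompetitiveSeries.from_records(
        list(zip(is_copies, ratio * is_mol, is_mol)), extraction_id
    )


def recipe_volumes(
    targets: dict[str, float], extraction_concentrations: dict[str, float]
) -> pd.DataFrame:
    """Extraction volumes (ul) delivering the target copies per species.

    ``volume = copies / concentration`` with concentration in copies/ul.
    Returns a table with a trailing TOTAL row.
    """
    rows = []
    for species, copies in targets.items():
        conc = extraction_concentrations.get(species)
        if conc is None:
            raise ValueError(f"no extraction concentration for {species!r}")
        if conc <= 0:
            raise ValueError(f"non-positive concentration for {species!r}")
        rows.append(
            dict(
                species=species,
                copies=copies,
                concentration=conc,
                volume_ul=copies / conc,
            )
        )
    df = pd.DataFrame(rows, columns=["species", "copies", "concentration", "volume_ul"])
    total = pd.DataFrame(
        [
            dict(
                species="TOTAL",
                copies=df["copies"].sum(),
                concentration=float("nan"),
                volume_ul=df["volume_ul"].sum(),
            )
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def design_internal_standard(
    amplicon: str,
    deletion_fraction: float = 0.10,
    fwd_site_len: int = 20,
    rev_site_len: int = 20,
) -> str:
    """Derive an internal-standard sequence by a centered interior deletion.

    Removes ``round(deletion_fraction * len(amplicon))`` bases from the
    center of the insert, leaving both primer annealing sites untouched, so
    the standard is ``deletion_fraction`` shorter than the native amplicon
    (10% by default, enough for electrophoretic separation without
    altering PCR efficiency).
    """
    if not 0.0 < deletion_fraction < 0.5:
        raise ValueError("deletion_fraction must be in (0, 0.5)")
    bad = set(amplicon.upper()) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"amplicon has invalid characters: {sorted(bad)}")
    amplicon = amplicon.upper()
    insert_len = len(amplicon) - fwd_site_len - rev_site_len
    if insert_len <= 0:
        raise ValueError("primer sites cover the whole amplicon")
    deletion = round(deletion_fraction * len(amplicon))
    if deletion >= insert_len:
        raise ValueError(
            f"deletion of {deletion} bp would reach a primer site "
            f"(insert is {insert_len} bp)"
        )
    insert = amplicon[fwd_site_len : len(amplicon) - rev_site_len]
    start = (insert_len - deletion) // 2
    new_insert = insert[:start] + insert[start + deletion :]
    return amplicon[:fwd_site_len] + new_insert + amplicon[len(amplicon) - rev_site_len :]
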