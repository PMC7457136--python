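"""Expression quantification: qPCR standard curves, RPKM and the Rj statistic.

Absolute qPCR quantification regresses the cycle threshold Ct on
log10(template copies) over a 10-fold plasmid dilution series and inverts
the fit for unknowns; the amplification efficiency follows from the slope
as E = 10^(-1/slope) - 1 (a perfect doubling per cycle gives slope
-1/log10(2) ~ -3.32 and E = 1).  Tissue expression is reported relative to
a reference tissue (100%) with a two-tailed Student's t-test.

For count data, RPKM = 1e9 * count / (library_size * gene_length_bp), and
departure of a gene's counts from proportionality to library sizes is
measured by the log-likelihood ratio statistic

    R_j = sum_i x_ij * ln( x_ij / (N_i * f_j) ),   f_j = sum_i x_ij / sum_i N_i

with zero counts contributing zero.  R_j = 0 iff counts are exactly
proportional to library sizes; larger values indicate library-specific
(e.g. tissue-specific) expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DilutionPoint:
    copies: float
    ct: float

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValueError(f"copies must be positive, got {self.copies}")


@dataclass
class StandardCurve:
    """Linear fit of Ct against log10(copies)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: Sequence[DilutionPoint]) -> StandardCurve:
    """Least-squares fit of Ct vs log10(copies) over a dilution series."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 dilution points, got {len(points)}")
    copies = np.array([p.copies for p in points], dtype=float)
    cts = np.array([p.ct for p in points], dtype=float)
    if len(np.unique(copies)) < 3:
        raise ValueError("need >= 3 distinct copy numbers in the dilution series")
    res = stats.linregress(np.log10(copies), cts)
    return StandardCurve(slope=res.slope, intercept=res.intercept,
                         r_squared=res.rvalue ** 2)


def quantify_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept) / slope)."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope; cannot invert")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def copies_from_cts(cts: Sequence[float], curve: StandardCurve) -> float:
    """Quantify a technical-replicate group: mean Ct first, then invert."""
    if len(cts) == 0:
        raise ValueError("empty Ct group")
    return quantify_copies(float(np.mean(cts)), curve)


def relative_expression(
    copies_by_tissue: dict[str, Sequence[float]],
    reference_tissue: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Express each tissue relative to a reference tissue (its mean = 100%).

    ``copies_by_tissue`` maps tissue name to replicate copy numbers.  The
    p-value is a two-sample, two-tailed Student's t-test (equal variance by
    default; set ``equal_var=False`` for Welch) of each tissue's replicates
    against the reference's.  With fewer than 2 replicates on either side
    the percentage is still reported and p is missing (NaN).
    """
    if reference_tissue not in copies_by_tissue:
        raise ValueError(f"reference tissue {reference_tissue!r} not present")
    ref = np.asarray(copies_by_tissue[reference_tissue], dtype=float)
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError("reference tissue mean must be positive")
    rows = []
    for tissue, values in copies_by_tissue.items():
        vals = np.asarray(values, dtype=float)
        mean = float(np.mean(vals))
        if len(vals) >= 2 and len(ref) >= 2:
            p = float(stats.ttest_ind(vals, ref, equal_var=equal_var).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "tissue": tissue,
                "n_replicates": len(vals),
                "mean_copies": mean,
                "percent_of_reference": 100.0 * mean / ref_mean,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def rpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError(f"gene length must be positive, got {gene_length_bp}")
    if library_size <= 0:
        raise ValueError(f"library size must be positive, got {library_size}")
    return 1e9 * count / (library_size * gene_length_bp)


def rj_statistic(counts: Sequence[float], library_sizes: Sequence[float]) -> float:
    """Log-likelihood ratio for departure from proportional representation.

    ``counts`` are one gene's read counts across libraries, ``library_sizes``
    the total mapped reads per library.  Returns NaN for an all-zero gene
    (the statistic is undefined there).
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(library_sizes, dtype=float)
    if x.shape != n.shape:
        raise ValueError("counts and library_sizes must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 libraries")
    if np.any(n <= 0):
        raise ValueError("library sizes must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("counts must satisfy 0 <= x_ij <= N_i")
    total = x.sum()
    if total == 0:
        return float("nan")
    f = total / n.sum()
    nz = x > 0
    return float(np.sum(x[nz] * np.log(x[nz] / (n[nz] * f))))


def rj_table(count_matrix: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Rj per gene for a genes x libraries count matrix.

    ``library_sizes`` is indexed by the matrix's columns.
    """
    sizes = library_sizes.reindex(count_matrix.columns)
    if sizes.isna().any():
        missing = list(sizes[sizes.isna()].index)
        raise ValueError(f"library sizes missing for: {missing}")
    values = [
        rj_statistic(count_matrix.loc[g].to_numpy(), sizes.to_numpy())
        for g in count_matrix.index
    ]
    return pd.DataFrame({"gene": count_matrix.index, "Rj": values}).set_index("gene")
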