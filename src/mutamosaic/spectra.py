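"""Mutation-spectrum classification and exact between-group comparisons.

Each unique mutation falls into one of eight categories: the six base
substitutions written with a purine reference (a C→A event on the plus strand
is the same lesion as G→T on the other, so pyrimidine-reference substitutions
are complemented), plus insertions and deletions.  BaP's hallmark is an excess
of G→T transversions from bulky guanine adducts.

Spectra are compared as category-by-group contingency tables with exact
conditional tests: full hypergeometric enumeration when the table collapses to
2x2, and a seeded Monte-Carlo exact test (tables drawn with fixed margins,
two-sided probability-ordering rule) for larger tables, with Bonferroni
correction across the comparisons performed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .pileup import complement

CATEGORIES = ("G>T", "G>C", "G>A", "A>T", "A>G", "A>C", "INS", "DEL")
SUBSTITUTION_CATEGORIES = CATEGORIES[:6]
_PURINES = "AG"
# relative tolerance when comparing table probabilities (as in R's fisher.test)
_REL_TOL = 1e-7


def classify(ref: str, alt: str) -> str:
    """Map a (ref, alt) event to its spectrum category.

    ``alt`` is a base letter, an insertion key ``"+SEQ"`` or a deletion key
    ``"-SEQ"``.  Substitutions with a pyrimidine reference are complemented to
    the purine-reference form.
    """
    if alt.startswith("+"):
        return "INS"
    if alt.startswith("-"):
        return "DEL"
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError("alternate equals reference")
    if ref not in _PURINES:
        ref, alt = complement(ref), complement(alt)
    return f"{ref}>{alt}"


@dataclasses.dataclass
class Spectrum:
    """Category counts for one group of unique mutations."""

    group: object
    counts: pd.Series  # indexed by CATEGORIES

    @property
    def n_unique(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        n = self.n_unique
        return self.counts / n if n else self.counts * np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": str(self.group),
                "category": self.counts.index,
                "count": self.counts.to_numpy(),
                "proportion": self.proportions.to_numpy(),
            }
        )


def spectrum(calls: pd.DataFrame, group=None, weighting: str = "unique") -> Spectrum:
    """Tally spectrum categories from a call table with ref/alt columns.

    ``weighting="unique"`` counts each unique mutation once (the default);
    ``"by_corrected_count"`` weights by the corrected plaque count as a
    sensitivity analysis.
    """
    if weighting not in ("unique", "by_corrected_count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for _, row in calls.iterrows():
        cat = classify(row["ref"], row["alt"])
        w = int(row["corrected_count"]) if weighting == "by_corrected_count" else 1
        counts[cat] += w
    return Spectrum(group=group, counts=counts)


@dataclasses.dataclass
class SpectrumComparison:
    p_value: float
    p_bonferroni: float
    method: str  # "exact-2x2" or "monte-carlo"
    seed: int | None
    n_resamples: int | None
    table: np.ndarray


def exact_2x2_p(table: np.ndarray) -> float:
    """Two-sided hypergeometric p: total probability of tables no more likely
    than the observed one, margins fixed (full enumeration)."""
    r0, r1 = table.sum(axis=1)
    c0 = table[:, 0].sum()
    N = r0 + r1
    rv = hypergeom(N, r0, c0)
    support = np.arange(max(0, c0 - r1), min(r0, c0) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table[0, 0])
    return float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())


def _log_table_prob(x: np.ndarray, row_totals: np.ndarray) -> np.ndarray:
    """Unnormalised log probability of r x 2 tables with fixed margins.

    ``x`` holds first-column counts, shape (..., r).
    """
    r = row_totals.astype(float)
    return (
        gammaln(r + 1) - gammaln(x + 1) - gammaln(r - x + 1)
    ).sum(axis=-1)


def monte_carlo_p(table: np.ndarray, seed: int, n_resamples: int) -> float:
    row_totals = table.sum(axis=1)
    c0 = int(table[:, 0].sum())
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(row_totals, c0, size=n_resamples)
    logp = _log_table_prob(draws.astype(float), row_totals)
    logp_obs = _log_table_prob(table[:, 0].astype(float), row_totals)
    hits = int((logp <= logp_obs + _REL_TOL).sum())
    return (1 + hits) / (1 + n_resamples)


def compare_table(table, seed: int = 0, n_resamples: int = 100_000):
    """Exact conditional test of an r x 2 category-by-group table.

    Returns (p, method).  All-zero rows are dropped; two remaining rows give
    the enumerated hypergeometric p, more give the seeded Monte-Carlo p.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return 1.0, "degenerate"
    if table.shape[0] == 2:
        return exact_2x2_p(table), "exact-2x2"
    return monte_carlo_p(table, seed, n_resamples), "monte-carlo"


def compare_spectra(
    a: Spectrum,
    b: Spectrum,
    n_comparisons: int = 1,
    seed: int = 0,
    n_resamples: int = 100_000,
    substitutions_only: bool = False,
) -> SpectrumComparison:
    """Exact test of whether two spectra share category proportions."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if list(a.counts.index) != list(b.counts.index):
        raise ValueError("spectra are over different category sets")
    cats = list(SUBSTITUTION_CATEGORIES) if substitutions_only else list(CATEGORIES)
    table = np.column_stack(
        [a.counts.loc[cats].to_numpy(), b.counts.loc[cats].to_numpy()]
    )
    p, method = compare_table(table, seed=seed, n_resamples=n_resamples)
    return SpectrumComparison(
        p_value=p,
        p_bonferroni=min(1.0, p * n_comparisons),
        method=method,
        seed=seed if method == "monte-carlo" else None,
        n_resamples=n_resamples if method == "monte-carlo" else None,
        table=table,
    )
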