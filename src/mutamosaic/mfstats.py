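"""Mutant-frequency dose-response statistics.

The transgenic-rodent endpoint is the mutant frequency (MF): mutant plaques
over total plaques for one animal and tissue, conventionally displayed
x 10^-5.  Dose response is modelled with a log-link quasi-Poisson GLM,

    mutants_i ~ quasiPoisson(mu_i),   log mu_i = x_i' beta + log(total_i),

so coefficients act on the mutation *rate* and exp(beta_d) is the fold change
of dose group d over control.  Over-dispersion between animals is absorbed by
the Pearson dispersion phi = X^2 / (n - p); standard errors are Poisson
standard errors scaled by sqrt(phi), and inference uses Wald t statistics on
n - p degrees of freedom with Bonferroni correction over the dose contrasts.

The model is exposed statsmodels-style: build a :class:`MutantFrequencyModel`
from a per-animal table, ``fit()`` it, and read estimates, fold changes and a
``summary()`` table off the returned :class:`DoseResponseResults`.

A Poisson-rate homogeneity likelihood-ratio screen
(:func:`lrt_outlier_screen`) flags discordant technical replicates within
animals, then discordant animals within dose groups; removal is opt-in and
every test and removal is returned in a trace, never silent.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("animal_id", "tissue", "dose", "mutants", "total")


@dataclasses.dataclass(frozen=True)
class MFRecord:
    """Per-animal (or per-replicate) mutant and total plaque counts."""

    animal_id: str
    tissue: str
    dose: float
    mutants: int
    total: int
    replicate_id: str | None = None

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total plaques must be positive")
        if not 0 <= self.mutants <= self.total:
            raise ValueError("mutants must be in [0, total]")


def mutant_frequency(record_or_mutants, total=None) -> float:
    """Mutant frequency mutants / total (display convention: x 10^-5)."""
    if total is None:
        r = record_or_mutants
        mutants, total = r.mutants, r.total
    else:
        mutants = record_or_mutants
    if total <= 0:
        raise ValueError("total plaques must be positive")
    return mutants / total


def group_mutant_frequency(df: pd.DataFrame, by=("tissue", "dose")) -> pd.DataFrame:
    """Pooled group MF = sum(mutants) / sum(total), not the mean of animal MFs."""
    g = df.groupby(list(by), sort=True)[["mutants", "total"]].sum().reset_index()
    g["mf"] = g["mutants"] / g["total"]
    return g


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


class MutantFrequencyModel:
    """Quasi-Poisson dose-response GLM with log(total plaques) offset.

    Parameters
    ----------
    data : DataFrame with columns animal_id, tissue, dose, mutants, total
        (one tissue at a time).
    dose_coding : "factor" (one coefficient per non-control dose; control must
        be present) or "continuous" (a single per-unit-dose trend slope).
    """

    def __init__(self, data: pd.DataFrame, dose_coding: str = "factor"):
        missing = [c for c in ("dose", "mutants", "total") if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if dose_coding not in ("factor", "continuous"):
            raise ValueError(f"unknown dose_coding {dose_coding!r}")
        if "tissue" in data.columns and data["tissue"].nunique() > 1:
            raise ValueError("fit one tissue at a time")
        self.data = data.reset_index(drop=True)
        self.dose_coding = dose_coding
        self.endog = self.data["mutants"].to_numpy(dtype=float)
        self.offset = np.log(self.data["total"].to_numpy(dtype=float))
        doses = self.data["dose"].to_numpy(dtype=float)
        levels = np.unique(doses)
        if len(levels) < 2:
            raise ValueError("need at least 2 dose levels")
        if dose_coding == "factor":
            if 0.0 not in levels:
                raise ValueError("factor coding requires a control (dose 0) group")
            self.dose_levels = levels
            self.exog_names = ["Intercept"] + [f"dose[{d:g}]" for d in levels[1:]]
            X = np.column_stack(
                [np.ones_like(doses)] + [(doses == d).astype(float) for d in levels[1:]]
            )
        else:
            self.dose_levels = levels
            self.exog_names = ["Intercept", "dose"]
            X = np.column_stack([np.ones_like(doses), doses])
        self.exog = X

    @classmethod
    def from_records(cls, records, **kwargs) -> "MutantFrequencyModel":
        return cls(records_frame(records), **kwargs)

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "DoseResponseResults":
        """Iteratively reweighted least squares for the log-link Poisson score."""
        y, X, offset = self.endog, self.exog, self.offset
        n, p = X.shape
        for d in self.dose_levels:
            mask = self.data["dose"].to_numpy() == d
            if self.dose_coding == "factor" and y[mask].sum() == 0:
                warnings.warn(
                    f"dose level {d:g} has all-zero mutant counts; "
                    "its estimate is unstable"
                )
        mu = np.maximum(y, 0.5)
        eta = np.log(mu)
        beta = np.zeros(p)
        trace = []
        dev_prev = np.inf
        for it in range(1, maxiter + 1):
            W = mu
            z = eta + (y - mu) / mu - offset
            WX = X * W[:, None]
            xtwx = X.T @ WX
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
            delta = np.max(np.abs(beta_new - beta)) if it > 1 else np.inf
            beta = beta_new
            eta = X @ beta + offset
            mu = np.exp(eta)
            with np.errstate(divide="ignore", invalid="ignore"):
                dev_terms = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
            dev = 2.0 * float(np.sum(dev_terms - (y - mu)))
            trace.append((it, beta.copy(), delta, dev))
            if delta < tol:
                break
            # a dose group with zero mutants drives its coefficient to -inf
            # while the fitted means converge: accept on a stable deviance,
            # but only once some fitted mean has actually collapsed to zero
            if mu.min() < 1e-10 and abs(dev - dev_prev) < tol * (abs(dev) + 0.1):
                break
            dev_prev = dev
        else:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations", trace
            )
        xtwx = X.T @ (X * mu[:, None])
        cov_unscaled = np.linalg.inv(xtwx)
        pearson = float(np.sum((y - mu) ** 2 / mu))
        df_resid = n - p
        dispersion = pearson / df_resid if df_resid > 0 else np.nan
        return DoseResponseResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_unscaled=cov_unscaled,
            dispersion=dispersion,
            pearson_chi2=pearson,
            df_resid=df_resid,
            fittedvalues=mu,
            n_iter=it,
        )


@dataclasses.dataclass
class DoseResponseResults:
    """Fit artefacts for a mutant-frequency dose-response GLM."""

    model: MutantFrequencyModel
    params: pd.Series
    cov_unscaled: np.ndarray
    dispersion: float
    pearson_chi2: float
    df_resid: int
    fittedvalues: np.ndarray
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        scale = self.dispersion if np.isfinite(self.dispersion) else 1.0
        return pd.Series(
            np.sqrt(np.maximum(scale, 0.0) * np.diag(self.cov_unscaled)),
            index=self.params.index,
        )

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues
        return pd.Series(
            2 * stats.t.sf(np.abs(t.to_numpy()), self.df_resid), index=t.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.params - crit * self.bse
        hi = self.params + crit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def fold_changes(self, alpha: float = 0.05, n_comparisons: int | None = None) -> pd.DataFrame:
        """Per-dose fold change exp(beta_d) with t CIs and Bonferroni p.

        The Bonferroni multiplier defaults to the number of non-control dose
        contrasts in the model (the study's per-tissue comparisons).
        """
        if self.model.dose_coding != "factor":
            raise ValueError("fold changes per dose require factor coding")
        names = self.params.index[1:]
        if n_comparisons is None:
            n_comparisons = len(names)
        ci = self.conf_int(alpha).loc[names]
        p = self.pvalues.loc[names]
        return pd.DataFrame(
            {
                "dose": self.model.dose_levels[1:],
                "fold": np.exp(self.params.loc[names].to_numpy()),
                "ci_lower": np.exp(ci["lower"].to_numpy()),
                "ci_upper": np.exp(ci["upper"].to_numpy()),
                "p_value": p.to_numpy(),
                "p_bonferroni": np.minimum(1.0, p.to_numpy() * n_comparisons),
            },
            index=names,
        )

    def trend(self) -> pd.Series:
        """Continuous-dose trend: per-unit-dose rate ratio and its p-value."""
        if self.model.dose_coding != "continuous":
            raise ValueError("trend requires continuous dose coding")
        return pd.Series(
            {
                "slope": self.params["dose"],
                "rate_ratio_per_unit": float(np.exp(self.params["dose"])),
                "p_value": self.pvalues["dose"],
            }
        )

    def summary(self) -> str:
        lines = [
            "Quasi-Poisson dose-response GLM (log link, offset log total plaques)",
            f"  observations: {len(self.model.endog)}   dose coding: {self.model.dose_coding}",
            f"  dispersion (Pearson X2/df): {self.dispersion:.4f}   df_resid: {self.df_resid}"
            f"   IRLS iterations: {self.n_iter}",
            "",
            f"  {'term':<12}{'coef':>10}{'se':>10}{'t':>9}{'p':>11}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<12}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>11.3g}"
            )
        if self.model.dose_coding == "factor":
            lines.append("")
            lines.append(
                f"  {'dose':>6}{'fold':>9}{'95% CI':>20}{'p':>11}{'p_bonf':>11}"
            )
            for _, row in self.fold_changes().iterrows():
                ci = f"[{row.ci_lower:.2f}, {row.ci_upper:.2f}]"
                lines.append(
                    f"  {row.dose:>6g}{row.fold:>9.2f}{ci:>20}"
                    f"{row.p_value:>11.3g}{row.p_bonferroni:>11.3g}"
                )
        return "\n".join(lines)


def fit_quasipoisson(records, dose_coding: str = "factor") -> DoseResponseResults:
    """Functional wrapper: fit the dose-response GLM from records or a frame."""
    data = records if isinstance(records, pd.DataFrame) else records_frame(records)
    return MutantFrequencyModel(data, dose_coding=dose_coding).fit()


# ---------------------------------------------------------------------------
# likelihood-ratio outlier screen


def homogeneity_lrt(mutants, totals):
    """Poisson-rate homogeneity LRT across k units sharing one rate.

    G = 2 sum_i y_i log(y_i / yhat_i) with yhat_i = total_i * (sum y / sum
    total); zero counts contribute nothing.  Returns (G, df, p) with df = k-1
    against chi-square.
    """
    y = np.asarray(mutants, dtype=float)
    t = np.asarray(totals, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 units")
    yhat = t * (y.sum() / t.sum())
    pos = y > 0
    G = 2.0 * float(np.sum(y[pos] * np.log(y[pos] / yhat[pos])))
    df = y.size - 1
    return G, df, float(stats.chi2.sf(G, df))


def _deviance_residuals(y, yhat):
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / yhat), 0.0)
    dev = 2.0 * (term - (y - yhat))
    return np.sign(y - yhat) * np.sqrt(np.maximum(dev, 0.0))


def lrt_outlier_screen(units: pd.DataFrame, alpha: float = 0.05):
    """Iteratively drop the most discordant unit while homogeneity is rejected.

    ``units`` is a frame with ``mutants`` and ``total`` columns, all sharing
    one nesting key (replicates of one animal, or animals of one dose group).
    While the homogeneity LRT rejects at ``alpha``, the unit with the largest
    absolute deviance residual is removed; the screen stops once the test
    accepts or fewer than two units remain (a rejecting pair loses its more
    discordant member).  Returns (kept, removed, trace); with fewer than two
    units the screen is a no-op with a warning.
    """
    kept = units.reset_index(drop=True).copy()
    removed = kept.iloc[0:0].copy()
    trace = []
    if len(kept) < 2:
        warnings.warn("fewer than 2 units: outlier screen skipped")
        return kept, removed, trace
    while len(kept) >= 2:
        y = kept["mutants"].to_numpy(dtype=float)
        t = kept["total"].to_numpy(dtype=float)
        G, df, p = homogeneity_lrt(y, t)
        step = {"k": len(kept), "G": G, "df": df, "p": p, "removed": None}
        if p >= alpha:
            trace.append(step)
            break
        resid = _deviance_residuals(y, t * (y.sum() / t.sum()))
        worst = int(np.argmax(np.abs(resid)))
        step["removed"] = kept.iloc[worst].to_dict()
        trace.append(step)
        removed = pd.concat([removed, kept.iloc[[worst]]], ignore_index=True)
        kept = kept.drop(kept.index[worst]).reset_index(drop=True)
    return kept, removed, trace


def screen_records(df: pd.DataFrame, alpha: float = 0.05):
    """Two-stage screen: replicates within animals, then animals within groups.

    Stage 1 runs the LRT screen across technical replicates of each
    (tissue, animal); surviving replicates are summed per animal.  Stage 2
    screens the per-animal counts within each (tissue, dose) group.  Returns
    (screened per-animal frame, trace list); every decision is in the trace.
    """
    trace = []
    stage1_parts = []
    for (tissue, animal), g in df.groupby(["tissue", "animal_id"], sort=True):
        if len(g) >= 2:
            kept, _, t = lrt_outlier_screen(g, alpha=alpha)
            trace.append({"stage": "replicates", "tissue": tissue,
                          "animal_id": animal, "trace": t})
        else:
            kept = g
        stage1_parts.append(kept)
    per_rep = pd.concat(stage1_parts, ignore_index=True)
    per_animal = (
        per_rep.groupby(["tissue", "dose", "animal_id"], sort=True)[["mutants", "total"]]
        .sum()
        .reset_index()
    )
    stage2_parts = []
    for (tissue, dose), g in per_animal.groupby(["tissue", "dose"], sort=True):
        if len(g) >= 2:
            kept, _, t = lrt_outlier_screen(g, alpha=alpha)
            trace.append({"stage": "animals", "tissue": tissue,
                          "dose": dose, "trace": t})
        else:
            kept = g
        stage2_parts.append(kept)
    return pd.concat(stage2_parts, ignore_index=True), trace
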