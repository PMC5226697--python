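"""Parameter-recovery experiments on synthetic data.

Each function generates ground-truthed data under the study conditions,
runs the corresponding pipeline stage, and scores the estimates against the
generating parameters.  They back both the acceptance checks and the CLI's
recovery report; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import BackgroundModel, PlaquePoolSample, call_mutations, calling_threshold
from .clonality import ClonalityCalibration, correct_count, raw_count, summarize_clonality
from .mfstats import MutantFrequencyModel, homogeneity_lrt, lrt_outlier_screen
from .simulate import SimConfig, make_reference, simulate_cohort, simulate_pool_and_reads
from .spectra import exact_2x2_p, monte_carlo_p

#: top-dose fold changes used as generating effects in the recovery loop:
#: sperm (at 20 mg/kg/day), bone marrow, brain and liver (at 40 mg/kg/day)
GENERATING_FOLDS = ((3.0, 20.0), (16.0, 40.0), (18.0, 40.0), (33.0, 40.0))


def fold_change_recovery(
    folds=GENERATING_FOLDS,
    n_replicates: int = 200,
    animals_per_group: int = 5,
    seed_base: int = 0,
) -> pd.DataFrame:
    """Fit the dose-response GLM on seeded two-group cohorts.

    For each generating fold F at dose d, cohorts of ``animals_per_group``
    control and treated animals are simulated under the default over-dispersed
    conditions with seeds ``seed_base + 1 .. seed_base + n_replicates``; each
    is fitted with dose as factor.  Returns one row per fold with the
    geometric and arithmetic means of the fold estimate and the empirical
    coverage of the 95% Wald t intervals.
    """
    rows = []
    for fold, dose in folds:
        log_ests, ests, covered = [], [], 0
        for i in range(1, n_replicates + 1):
            cfg = SimConfig(
                seed=seed_base + i,
                doses=(0.0, dose),
                animals_per_dose=animals_per_group,
                fold_per_dose={0.0: 1.0, dose: fold},
            )
            records, _ = simulate_cohort(cfg)
            fc = MutantFrequencyModel(records).fit().fold_changes().iloc[0]
            ests.append(fc.fold)
            log_ests.append(np.log(fc.fold))
            covered += int(fc.ci_lower <= fold <= fc.ci_upper)
        rows.append(
            {
                "true_fold": fold,
                "dose": dose,
                "geometric_mean": float(np.exp(np.mean(log_ests))),
                "arithmetic_mean": float(np.mean(ests)),
                "ci_coverage": covered / n_replicates,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)


def caller_recovery(seed: int = 0, artifact_rate: float = 0.04) -> dict:
    """Score the caller against simulator truth under the study conditions.

    Pools of clonally expanded mutations (every true proportion at least
    2/n_plaques, i.e. twice the calling threshold) are sequenced in duplicate
    at 20,000x with 0.1% per-base error, plus one systematic artifact injected
    into every library.  Returns sensitivity, precision, whether the artifact
    was removed from every sample by the 2% background filter, and whether
    the called set grew monotonically under threshold/background sweeps.
    """
    base = SimConfig(seed=seed)
    reference = make_reference(base)
    artifact_pos = next(
        p for p in range(1, len(reference) + 1) if reference[p - 1] == "G"
    )
    cfg = SimConfig(
        seed=seed,
        animals_per_dose=2,
        clonal_fraction=1.0,
        n_plaques_pooled=60,
        coverage=20_000,
        error_rate=0.001,
        artifact_sites=((artifact_pos, "T", artifact_rate),),
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    records, _ = simulate_cohort(cfg, rng)
    samples, libraries, truths = [], {}, []
    for _, rec in records.iterrows():
        s = PlaquePoolSample(
            sample_id=str(rec.animal_id), animal_id=str(rec.animal_id),
            tissue=rec.tissue, dose=float(rec.dose), n_plaques=cfg.n_plaques_pooled,
            library_ids=(f"{rec.animal_id}_r1", f"{rec.animal_id}_r2"),
        )
        rep1, rep2, truth = simulate_pool_and_reads(cfg, s, reference, rng=rng)
        samples.append(s)
        libraries[s.library_ids[0]] = rep1
        libraries[s.library_ids[1]] = rep2
        truths.append(truth)
    truth_all = pd.concat(truths, ignore_index=True)
    bg = BackgroundModel.from_libraries(libraries.values())

    tp = fp = fn = 0
    artifact_removed = True
    monotone = True
    for s in samples:
        rep1, rep2 = libraries[s.library_ids[0]], libraries[s.library_ids[1]]
        calls = call_mutations(s, rep1, rep2, bg=bg)
        called = {(c.position, c.alt) for c in calls}
        t = truth_all[truth_all.sample_id == s.sample_id]
        true_keys = set(zip(t.position, t.alt))
        tp += len(called & true_keys)
        fp += len(called - true_keys)
        fn += len(true_keys - called)
        if (artifact_pos, "T") in called:
            artifact_removed = False
        # monotonicity: larger pools (lower thresholds) and laxer background
        # cutoffs only ever add calls
        prev: set = set()
        for n_plaques in (30, 60, 300):
            s_n = PlaquePoolSample(
                sample_id=s.sample_id, animal_id=s.animal_id, tissue=s.tissue,
                dose=s.dose, n_plaques=n_plaques, library_ids=s.library_ids,
            )
            got = {
                (c.position, c.alt)
                for c in call_mutations(s_n, rep1, rep2, bg=bg)
            }
            monotone &= prev <= got
            prev = got
        prev = set()
        for cutoff in (0.005, 0.02, 1.0):
            got = {
                (c.position, c.alt)
                for c in call_mutations(s, rep1, rep2, bg=bg, background_cutoff=cutoff)
            }
            monotone &= prev <= got
            prev = got
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_true": int(len(truth_all)),
        "artifact_background_rate": bg.rate(artifact_pos, "T"),
        "artifact_always_removed": bool(artifact_removed),
        "monotone_under_sweeps": bool(monotone),
    }


def clonality_recovery(seed: int = 0, n_groups: int = 4,
                       clonal_fraction: float = 0.4) -> dict:
    """Recover the generating clonal fraction from corrected plaque counts.

    One pool of ~200 unique mutations per group, sequenced in the simulator's
    deterministic-read mode (read proportions equal true plaque proportions
    exactly); raw counts at the truth positions are corrected with the default
    identity/LOD calibration and summarised per group.  Under read noise a
    size-2 clone's raw count is centred exactly on the LOD, so the noisy-mode
    estimate is biased low by construction; the deterministic mode isolates
    the correction logic itself.
    """
    cfg = SimConfig(
        seed=seed,
        clonal_fraction=clonal_fraction,
        # ~220 unique mutations at mean clone size 1.8; 400 divides the
        # 20,000x coverage so expected-mode read counts are exact integers
        n_plaques_pooled=400,
        error_rate=0.0,
        count_sampling="expected",
    )
    reference = make_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    cal = ClonalityCalibration.identity()
    frames = []
    for g in range(n_groups):
        s = PlaquePoolSample(
            sample_id=f"g{g}", animal_id=f"g{g}", tissue="bone_marrow",
            dose=20.0 + g, n_plaques=cfg.n_plaques_pooled,
            library_ids=(f"g{g}_r1", f"g{g}_r2"),
        )
        rep1, rep2, truth = simulate_pool_and_reads(
            cfg, s, reference, condition="bap", rng=rng
        )
        rows = []
        for _, row in truth.iterrows():
            mean_p = 0.5 * (
                rep1.proportion(row.position, row.alt)
                + rep2.proportion(row.position, row.alt)
            )
            raw = raw_count(mean_p, s.n_plaques)
            rows.append(
                {
                    "tissue": s.tissue,
                    "dose": s.dose,
                    "true_count": row.true_count,
                    "raw_count": raw,
                    "corrected_count": correct_count(raw, cal),
                }
            )
        frames.append(pd.DataFrame(rows))
    calls = pd.concat(frames, ignore_index=True)
    summary = summarize_clonality(calls)
    return {
        "generating_fraction": clonal_fraction,
        "per_group_estimates": summary["proportion_expanded"].tolist(),
        "per_group_n_unique": summary["n_unique"].tolist(),
        "max_abs_error": float(
            (summary["proportion_expanded"] - clonal_fraction).abs().max()
        ),
        "singletons_preserved": bool(
            (calls.loc[calls.true_count == 1, "corrected_count"] == 1).all()
        ),
        "corrected_at_least_one": bool((calls["corrected_count"] >= 1).all()),
    }


def mc_exact_agreement(seed: int = 0, n_resamples: int = 100_000,
                       totals=(10, 16, 24, 30), stride: int = 4) -> dict:
    """Monte-Carlo vs enumerated hypergeometric p on a sweep of 2x2 margins.

    For each table total N the margins (r0, c0) are swept with the given
    stride (a runtime-bounded subset of all margins up to N = 30); for each
    margin two observed tables are tested, the near-expectation cell and the
    lower-extreme cell.  Per-table deviations are reported in Monte-Carlo
    standard-error units; across a few hundred independent tables the maximum
    of ~|N(0,1)| draws is expected to land between 3 and 4 SE, so calibration
    is summarised both as the fraction of tables within 3 SE and as the
    largest deviation.
    """
    devs = []
    n_tables = 0
    for N in totals:
        for r0 in range(1, N, stride):
            r1 = N - r0
            if r1 < 1:
                continue
            for c0 in range(1, N, stride):
                lo, hi = max(0, c0 - r1), min(r0, c0)
                for x in {int(round(r0 * c0 / N)), lo}:
                    x = min(max(x, lo), hi)
                    table = np.array([[x, r0 - x], [c0 - x, r1 - (c0 - x)]])
                    p_exact = exact_2x2_p(table)
                    p_mc = monte_carlo_p(table, seed=seed + n_tables, n_resamples=n_resamples)
                    se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_resamples)
                    devs.append(abs(p_mc - p_exact) / (se + 1 / n_resamples))
                    n_tables += 1
    devs = np.asarray(devs)
    return {
        "fraction_within_3se": float((devs <= 3.0).mean()),
        "max_deviation_se_units": float(devs.max()),
        "n_tables": n_tables,
    }


def lrt_screen_calibration(seed: int = 0, n_groups: int = 1000,
                           alpha: float = 0.05, mean_count: float = 20.0,
                           k: int = 4) -> dict:
    """Closed-form LRT check plus false-removal rate on homogeneous groups."""
    G, df, p = homogeneity_lrt([0, 10], [1000, 1000])
    rng = np.random.default_rng(seed)
    removals = 0
    for _ in range(n_groups):
        y = rng.poisson(mean_count, size=k)
        units = pd.DataFrame({"mutants": y, "total": [100_000] * k})
        _, removed, _ = lrt_outlier_screen(units, alpha=alpha)
        removals += int(len(removed) > 0)
    return {
        "G_0_vs_10": float(G),
        "p_0_vs_10": float(p),
        "false_removal_rate": removals / n_groups,
        "alpha": alpha,
        "n_groups": n_groups,
    }


def glm_mean_oracle(seed: int = 0, n_datasets: int = 100) -> dict:
    """Fitted-vs-observed group-mean agreement on random small cohorts.

    With dose as factor and the canonical log link, fitted group totals equal
    observed group totals exactly; returns the largest relative discrepancy
    across seeded random datasets, plus the dispersion of the worked
    [2,3,4] vs [20,30,40] example.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n_levels = int(rng.integers(2, 5))
        doses = np.repeat(np.arange(n_levels) * 10.0, rng.integers(2, 6))
        totals = rng.integers(5_000, 100_000, size=doses.size)
        mu = 5e-5 * totals * (1 + doses / 10.0)
        mutants = rng.poisson(mu) + 1
        df = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(doses.size)],
                "tissue": "t",
                "dose": doses,
                "mutants": mutants,
                "total": totals,
            }
        )
        res = MutantFrequencyModel(df).fit()
        for d in np.unique(doses):
            sel = doses == d
            obs = mutants[sel].sum()
            worst = max(worst, abs(res.fittedvalues[sel].sum() - obs) / obs)
    worked = pd.DataFrame(
        {
            "animal_id": list("abcdef"),
            "tissue": "t",
            "dose": [0, 0, 0, 40, 40, 40],
            "mutants": [2, 3, 4, 20, 30, 40],
            "total": [100_000] * 6,
        }
    )
    res = MutantFrequencyModel(worked).fit()
    return {
        "max_group_mean_rel_error": float(worst),
        "worked_example_dispersion": float(res.dispersion),
        "worked_example_fold": float(res.fold_changes()["fold"].iloc[0]),
        "n_datasets": n_datasets,
    }
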