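"""Ground-truthed synthetic data for every stage of the pipeline.

The generator emulates the study design end to end: pregnant dams dosed at
{0, 10, 20, 40} mg/kg/day, over-dispersed per-animal mutant frequencies
(gamma-mixed Poisson plaque counts), pools of mutant plaques carrying unique
lacZ mutations with clonal size structure, duplicate sequencing libraries with
per-base miscall error, and optional position-specific systematic artifacts.
Every simulated object is paired with its truth table so downstream estimates
can be scored against known parameters.

Generative model
----------------
* animal MF ~ Gamma(shape, mean = baseline_mf x fold(dose));
  mutants ~ Poisson(MF x total plaques).  shape = inf gives deterministic MF.
* a pool of ``n_plaques_pooled`` mutant plaques holds unique mutations whose
  plaque counts are 1 (singletons) or, for a ``clonal_fraction`` of
  mutations, 2 + Geometric(clonal_size_geom_p); sizes are drawn until they
  fill the pool exactly (the last size is truncated to fit).
* each mutation's category is drawn from the condition's spectrum weights and
  placed at a distinct reference position consistent with its category.
* per library, each alternate's read count is Binomial(coverage, q) with q =
  true plaque proportion plus error_rate/3 per non-reference base (or the
  rounded expectation in ``count_sampling="expected"`` mode); artifact sites
  add their rate in *both* libraries, mimicking systematic platform error.

All randomness flows from one integer seed through numpy Generator streams,
so a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import PlaquePoolSample
from .pileup import BASES, BaseCountMatrix, complement, write_pileup
from .spectra import CATEGORIES

#: qualitative spectrum weights: a G>T-dominated adduct signature for exposed
#: pools and a transition/deletion-rich spontaneous background for controls.
#: These mimic the shape of reported lacZ spectra, not printed numbers.
DEFAULT_SPECTRUM_WEIGHTS = {
    "control": {
        "G>T": 0.12, "G>C": 0.06, "G>A": 0.30, "A>T": 0.07, "A>G": 0.12,
        "A>C": 0.05, "INS": 0.05, "DEL": 0.23,
    },
    "bap": {
        "G>T": 0.45, "G>C": 0.15, "G>A": 0.12, "A>T": 0.06, "A>G": 0.05,
        "A>C": 0.03, "INS": 0.02, "DEL": 0.12,
    },
}


@dataclasses.dataclass
class SimConfig:
    """All tunable generating conditions for one synthetic experiment."""

    seed: int = 0
    reference_length: int = 3000
    doses: tuple = (0.0, 10.0, 20.0, 40.0)
    animals_per_dose: int = 5
    baseline_mf: float = 5e-5
    fold_per_dose: dict = dataclasses.field(
        default_factory=lambda: {0.0: 1.0, 10.0: 3.0, 20.0: 8.0, 40.0: 16.0}
    )
    overdispersion_shape: float = 10.0  # gamma shape for animal-level MF
    plaques_total_per_animal: int = 300_000
    n_plaques_pooled: int = 100
    clonal_fraction: float = 0.4
    clonal_size_geom_p: float = 0.5  # sizes 2 + Geometric(p) for clonal mutations
    spectrum_weights: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPECTRUM_WEIGHTS.items()}
    )
    coverage: int = 20_000
    error_rate: float = 0.001
    artifact_sites: tuple = ()  # (position, alt key or class, rate)
    count_sampling: str = "binomial"  # or "expected"
    tissue: str = "bone_marrow"

    def __post_init__(self):
        self.doses = tuple(float(d) for d in self.doses)
        self.fold_per_dose = {float(k): float(v) for k, v in self.fold_per_dose.items()}
        for name in ("baseline_mf", "clonal_fraction", "clonal_size_geom_p", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clonal_size_geom_p == 0.0:
            raise ValueError("clonal_size_geom_p must be > 0")
        for name in ("reference_length", "animals_per_dose",
                     "plaques_total_per_animal", "n_plaques_pooled", "coverage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.overdispersion_shape <= 0:
            raise ValueError("overdispersion_shape must be positive (inf allowed)")
        if self.count_sampling not in ("binomial", "expected"):
            raise ValueError(f"unknown count_sampling {self.count_sampling!r}")
        missing = [d for d in self.doses if d not in self.fold_per_dose]
        if missing:
            raise ValueError(f"fold_per_dose missing doses {missing}")
        for cond, w in self.spectrum_weights.items():
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"spectrum weights for {cond!r} must sum to 1")
            unknown = set(w) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown spectrum categories {unknown}")
        for pos, _, rate in self.artifact_sites:
            if not 1 <= int(pos) <= self.reference_length:
                raise ValueError("artifact position outside reference")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("artifact rate must be in [0, 1]")

    def condition(self, dose: float) -> str:
        return "control" if dose == 0 else "bap"

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "artifact_sites" in raw:
            raw["artifact_sites"] = tuple(tuple(a) for a in raw["artifact_sites"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["doses"] = list(self.doses)
        d["artifact_sites"] = [list(a) for a in self.artifact_sites]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def make_reference(cfg: SimConfig) -> str:
    """Deterministic random reference sequence for the configured seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    return "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.reference_length)])


def simulate_cohort(cfg: SimConfig, rng=None):
    """Per-animal mutant/total plaque counts plus the animal-level truth.

    Returns (records frame with animal_id/tissue/dose/mutants/total,
    truth frame with the latent per-animal MF).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rows, truth = [], []
    for dose in cfg.doses:
        mean_mf = cfg.baseline_mf * cfg.fold_per_dose[dose]
        for a in range(cfg.animals_per_dose):
            animal = f"d{dose:g}_a{a + 1}"
            if np.isinf(cfg.overdispersion_shape):
                mf = mean_mf
            else:
                shape = cfg.overdispersion_shape
                mf = rng.gamma(shape, mean_mf / shape)
            total = cfg.plaques_total_per_animal
            mutants = int(rng.poisson(mf * total))
            rows.append((animal, cfg.tissue, dose, mutants, total))
            truth.append((animal, cfg.tissue, dose, mf))
    records = pd.DataFrame(
        rows, columns=["animal_id", "tissue", "dose", "mutants", "total"]
    )
    truth = pd.DataFrame(truth, columns=["animal_id", "tissue", "dose", "true_mf"])
    return records, truth


def _draw_sizes(cfg: SimConfig, rng) -> list:
    """Clonal-structure plaque counts summing exactly to the pool size."""
    sizes, total = [], 0
    while total < cfg.n_plaques_pooled:
        remaining = cfg.n_plaques_pooled - total
        if rng.random() < cfg.clonal_fraction:
            size = 2 + rng.geometric(cfg.clonal_size_geom_p) - 1  # support {2,3,...}
            if remaining < 2 and sizes:
                # a clone cannot fit in a single remaining plaque: grow the
                # previous mutation rather than emitting a spurious singleton
                sizes[-1] += remaining
                break
            size = max(2, min(size, remaining)) if remaining >= 2 else remaining
        else:
            size = 1
        sizes.append(int(size))
        total += size
    return sizes


def _place_mutation(category: str, reference: str, used: set, rng):
    """Pick an unused position consistent with the category; return (pos, ref, alt)."""
    L = len(reference)
    for _ in range(20 * L):
        pos = int(rng.integers(1, L + 1))
        if pos in used:
            continue
        ref = reference[pos - 1]
        if category == "INS":
            return pos, ref, "+" + BASES[rng.integers(0, 4)]
        if category == "DEL":
            if pos == L:
                continue
            return pos, ref, "-" + reference[pos]
        pur, alt_pur = category.split(">")
        if ref == pur:
            return pos, ref, alt_pur
        if ref == complement(pur):
            return pos, ref, complement(alt_pur)
    raise RuntimeError("could not place mutation: reference positions exhausted")


def simulate_pool_truth(cfg: SimConfig, sample_id: str, condition: str,
                        reference: str, rng) -> pd.DataFrame:
    """Unique mutations of one plaque pool with their true plaque counts."""
    weights = cfg.spectrum_weights[condition]
    cats = list(weights)
    pvals = np.array([weights[c] for c in cats])
    sizes = _draw_sizes(cfg, rng)
    # true mutations avoid declared artifact sites: a real event on top of a
    # systematic artifact is unidentifiable by design
    used: set = {int(p) for p, _, _ in cfg.artifact_sites}
    rows = []
    for size in sizes:
        cat = cats[rng.choice(len(cats), p=pvals)]
        pos, ref, alt = _place_mutation(cat, reference, used, rng)
        used.add(pos)
        rows.append((sample_id, pos, ref, alt, cat, size))
    return pd.DataFrame(
        rows, columns=["sample_id", "position", "ref", "alt", "category", "true_count"]
    )


def _library_counts(cfg: SimConfig, truth: pd.DataFrame, reference: str,
                    library_id: str, rng) -> BaseCountMatrix:
    L = len(reference)
    m = BaseCountMatrix.empty(library_id, reference)
    cov = cfg.coverage
    m.depth[:] = cov
    ref_idx = np.array([BASES.index(b) for b in reference])
    # per-base miscall noise, spread evenly over the three non-reference bases
    if cfg.error_rate > 0 and cfg.count_sampling == "binomial":
        err = rng.binomial(cov, cfg.error_rate / 3.0, size=(L, 4))
        err[np.arange(L), ref_idx] = 0
        m.base_counts[:] = err
    # true events and systematic artifacts share one additive rate table
    extra: dict = {}
    for _, row in truth.iterrows():
        q = row.true_count / cfg.n_plaques_pooled
        extra[(int(row.position), row.alt)] = extra.get((int(row.position), row.alt), 0.0) + q
    for pos, alt, rate in cfg.artifact_sites:
        key = (int(pos), alt)
        extra[key] = extra.get(key, 0.0) + float(rate)
    for (pos, alt), q in extra.items():
        if cfg.count_sampling == "binomial":
            c = int(rng.binomial(cov, min(q, 1.0)))
        else:
            c = int(round(cov * q))
        if c == 0:
            continue
        if alt in BASES:
            m.base_counts[pos - 1, BASES.index(alt)] += c
        else:
            m.indels[(pos, alt)] = m.indels.get((pos, alt), 0) + c
    # remaining reads match the reference
    nonref = m.base_counts.sum(axis=1)
    m.base_counts[np.arange(L), ref_idx] += np.maximum(cov - nonref, 0)
    m.depth = np.maximum(m.depth, m.base_counts.sum(axis=1))
    m.validate()
    return m


def simulate_pool_and_reads(cfg: SimConfig, sample: PlaquePoolSample,
                            reference: str, condition: str | None = None,
                            rng=None, truth: pd.DataFrame | None = None):
    """Duplicate sequencing libraries for one plaque pool, plus its truth rows."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    if condition is None:
        condition = cfg.condition(sample.dose)
    if truth is None:
        truth = simulate_pool_truth(cfg, sample.sample_id, condition, reference, rng)
    libs = [
        _library_counts(cfg, truth, reference, lib_id, rng)
        for lib_id in sample.library_ids
    ]
    return libs[0], libs[1], truth


@dataclasses.dataclass
class SimulatedExperiment:
    """Everything one seeded run produces, with its ground truth."""

    config: SimConfig
    reference: str
    samples: list  # PlaquePoolSample per animal
    libraries: dict  # library_id -> BaseCountMatrix
    mf_records: pd.DataFrame
    truth_mutations: pd.DataFrame
    truth_animals: pd.DataFrame


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Full study: cohort plaque counts plus sequenced pools for every animal."""
    reference = make_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    mf_records, truth_animals = simulate_cohort(cfg, rng)
    samples, libraries, truths = [], {}, []
    for _, rec in mf_records.iterrows():
        sample = PlaquePoolSample(
            sample_id=str(rec.animal_id),
            animal_id=str(rec.animal_id),
            tissue=rec.tissue,
            dose=float(rec.dose),
            n_plaques=cfg.n_plaques_pooled,
            library_ids=(f"{rec.animal_id}_rep1", f"{rec.animal_id}_rep2"),
        )
        rep1, rep2, truth = simulate_pool_and_reads(
            cfg, sample, reference, rng=rng
        )
        samples.append(sample)
        libraries[rep1.library_id] = rep1
        libraries[rep2.library_id] = rep2
        truths.append(truth)
    return SimulatedExperiment(
        config=cfg,
        reference=reference,
        samples=samples,
        libraries=libraries,
        mf_records=mf_records,
        truth_mutations=pd.concat(truths, ignore_index=True),
        truth_animals=truth_animals,
    )


def simulate_calibration(cfg: SimConfig, true_counts=(1, 2, 4, 8, 16),
                         replicates: int = 4, rng=None) -> pd.DataFrame:
    """Calibration pools: observed raw counts for mutations of known size."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    reference = make_reference(cfg)
    rows = []
    for r in range(replicates):
        used: set = set()
        truth_rows = []
        for tc in true_counts:
            pos, ref, alt = _place_mutation("G>T", reference, used, rng)
            used.add(pos)
            truth_rows.append((f"cal{r}", pos, ref, alt, "G>T", int(tc)))
        truth = pd.DataFrame(
            truth_rows,
            columns=["sample_id", "position", "ref", "alt", "category", "true_count"],
        )
        m1 = _library_counts(cfg, truth, reference, f"cal{r}_rep1", rng)
        m2 = _library_counts(cfg, truth, reference, f"cal{r}_rep2", rng)
        for _, row in truth.iterrows():
            mean_p = 0.5 * (
                m1.proportion(row.position, row.alt) + m2.proportion(row.position, row.alt)
            )
            rows.append((mean_p * cfg.n_plaques_pooled, row.true_count))
    return pd.DataFrame(rows, columns=["observed_raw", "true_count"])


def write_experiment(exp: SimulatedExperiment, out_dir) -> Path:
    """Write the bundle as plain text: FASTA, pileups, sample sheet, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "reference.fa").write_text(">lacZ\n" + exp.reference + "\n")
    pileup_dir = out / "pileups"
    pileup_dir.mkdir(exist_ok=True)
    for lib_id, m in exp.libraries.items():
        write_pileup(m, pileup_dir / f"{lib_id}.pileup")
    sheet = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "animal_id": s.animal_id,
                "tissue": s.tissue,
                "dose": s.dose,
                "n_plaques": s.n_plaques,
                "library_1": s.library_ids[0],
                "library_2": s.library_ids[1],
            }
            for s in exp.samples
        ]
    )
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    exp.mf_records.to_csv(out / "mf_records.tsv", sep="\t", index=False)
    exp.truth_mutations.to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
    exp.truth_animals.to_csv(out / "truth_animals.tsv", sep="\t", index=False)
    exp.config.to_yaml(out / "config.yaml")
    return out
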