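"""Call unique lacZ mutations from paired technical-replicate libraries.

A pooled-plaque library mixes DNA from ``n_plaques`` mutant plaques, so a real
mutation carried by at least one whole plaque must appear in at least
``1/n_plaques`` of the reads.  A (position, alternate) event is therefore
called when

* its read proportion exceeds ``1/n_plaques`` in *both* technical-replicate
  libraries (strictly above the threshold), and
* its background rate across the experiment's libraries is below 2 %
  (systematic platform artifacts recur everywhere; true plaque mutations are
  private to one pool).

The background rate of an event class at a position is the median of its read
proportion across all libraries of the experiment, cases and controls alike;
the sample being called is not excluded (with half a dozen or more libraries
its own contribution cannot move the median past the cutoff by itself).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .clonality import ClonalityCalibration, correct_count, raw_count
from .pileup import AGGREGATE_CLASSES, BaseCountMatrix, aggregate_class

TISSUES = ("bone_marrow", "brain", "liver", "sperm", "testis", "other")

_CLASS_INDEX = {c: i for i, c in enumerate(AGGREGATE_CLASSES)}


@dataclasses.dataclass(frozen=True)
class PlaquePoolSample:
    """Metadata for one pool of mutant plaques sequenced in duplicate."""

    sample_id: str
    animal_id: str
    tissue: str
    dose: float  # mg/kg/day
    n_plaques: int  # mutant plaques pooled into the libraries
    library_ids: tuple

    def __post_init__(self):
        if self.n_plaques < 1:
            raise ValueError("n_plaques must be >= 1")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "library_ids", tuple(self.library_ids))
        if len(self.library_ids) != 2:
            raise ValueError(
                "exactly two technical-replicate libraries are required, got "
                f"{len(self.library_ids)}"
            )


def calling_threshold(sample) -> float:
    """Pooled mutation-calling threshold 1 / n_plaques.

    Accepts a :class:`PlaquePoolSample` or a plain plaque count.
    """
    n = sample.n_plaques if isinstance(sample, PlaquePoolSample) else int(sample)
    if n < 1:
        raise ValueError("number of plaques pooled must be >= 1")
    return 1.0 / n


@dataclasses.dataclass
class BackgroundModel:
    """Median per-library proportion of each aggregate class at each position."""

    rates: np.ndarray  # (L, 6) medians over libraries, classes A,C,G,T,INS,DEL
    n_libraries: int

    @classmethod
    def from_libraries(cls, libraries) -> "BackgroundModel":
        libraries = list(libraries)
        if len(libraries) < 2:
            raise ValueError("need at least 2 libraries to build a background model")
        L = len(libraries[0])
        if any(len(m) != L for m in libraries):
            raise ValueError("libraries cover references of different lengths")
        props = np.zeros((len(libraries), L, 6))
        for k, m in enumerate(libraries):
            d = m.depth.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = m.class_counts() / d[:, None]
            p[d == 0] = 0.0  # no coverage: no evidence of background
            props[k] = p
        return cls(rates=np.median(props, axis=0), n_libraries=len(libraries))

    def rate(self, pos: int, alt: str) -> float:
        """Background rate for a keyed event or aggregate class at ``pos``."""
        cls = alt if alt in _CLASS_INDEX else aggregate_class(alt)
        return float(self.rates[pos - 1, _CLASS_INDEX[cls]])


@dataclasses.dataclass
class MutationCall:
    """One unique (position, ref, alt) event called in a plaque pool."""

    position: int
    ref: str
    alt: str  # base letter, "+SEQ" insertion or "-SEQ" deletion
    proportion_rep1: float
    proportion_rep2: float
    mean_proportion: float
    raw_count: float
    corrected_count: int
    clonal: bool


def call_mutations(
    sample: PlaquePoolSample,
    rep1: BaseCountMatrix,
    rep2: BaseCountMatrix,
    bg: BackgroundModel | None = None,
    calibration: ClonalityCalibration | None = None,
    background_cutoff: float = 0.02,
) -> list:
    """Apply the pooled threshold, replicate intersection and background filter.

    Substitutions intersect replicates by (position, alternate base); indels
    must match anchor and sequence exactly.  Calls are returned sorted by
    position then alternate key, carrying raw and corrected plaque counts.
    """
    if len(rep1) != len(rep2) or rep1.reference != rep2.reference:
        raise ValueError("replicate libraries cover different references")
    if rep1.depth.sum() == 0 or rep2.depth.sum() == 0:
        raise ValueError("no usable coverage in a replicate library")
    if calibration is None:
        calibration = ClonalityCalibration.identity()
    thr = calling_threshold(sample)
    candidates = sorted(set(rep1.event_keys()) & set(rep2.event_keys()))
    calls = []
    for pos, alt in candidates:
        p1 = rep1.proportion(pos, alt)
        p2 = rep2.proportion(pos, alt)
        if not (p1 > thr and p2 > thr):
            continue
        if bg is not None and not bg.rate(pos, alt) < background_cutoff:
            continue
        mean_p = 0.5 * (p1 + p2)
        raw = raw_count(mean_p, sample.n_plaques)
        corrected = correct_count(raw, calibration)
        calls.append(
            MutationCall(
                position=pos,
                ref=rep1.ref_base(pos),
                alt=alt,
                proportion_rep1=float(p1),
                proportion_rep2=float(p2),
                mean_proportion=float(mean_p),
                raw_count=float(raw),
                corrected_count=corrected,
                clonal=corrected > 1,
            )
        )
    return calls


def calls_frame(calls, sample: PlaquePoolSample | None = None) -> pd.DataFrame:
    """Long-format call table, optionally annotated with sample metadata."""
    cols = [
        "position",
        "ref",
        "alt",
        "proportion_rep1",
        "proportion_rep2",
        "mean_proportion",
        "raw_count",
        "corrected_count",
        "clonal",
    ]
    df = pd.DataFrame([dataclasses.asdict(c) for c in calls], columns=cols)
    if sample is not None:
        df.insert(0, "sample_id", sample.sample_id)
        df.insert(1, "animal_id", sample.animal_id)
        df.insert(2, "tissue", sample.tissue)
        df.insert(3, "dose", sample.dose)
        df.insert(4, "n_plaques", sample.n_plaques)
    return df


def write_calls_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_vcf(calls, reference: str, path, sample_id: str = "sample", chrom: str = "lacZ") -> None:
    """Minimal VCF 4.2 emission of a call set (1-based, left-anchored indels)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(reference)}>",
        '##INFO=<ID=PROP1,Number=1,Type=Float,Description="Read proportion, replicate 1">',
        '##INFO=<ID=PROP2,Number=1,Type=Float,Description="Read proportion, replicate 2">',
        '##INFO=<ID=CCOUNT,Number=1,Type=Integer,Description="Corrected plaque count">',
        '##INFO=<ID=CLONAL,Number=0,Type=Flag,Description="Corrected count > 1">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda c: (c.position, c.alt)):
        anchor = reference[c.position - 1]
        if c.alt.startswith("+"):
            ref_field, alt_field = anchor, anchor + c.alt[1:]
        elif c.alt.startswith("-"):
            ref_field, alt_field = anchor + c.alt[1:], anchor
        else:
            ref_field, alt_field = c.ref, c.alt
        info = (
            f"PROP1={c.proportion_rep1:.6g};PROP2={c.proportion_rep2:.6g};"
            f"CCOUNT={c.corrected_count}" + (";CLONAL" if c.clonal else "")
        )
        lines.append(
            f"{chrom}\t{c.position}\t.\t{ref_field}\t{alt_field}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
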