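"""Read and write samtools-mpileup text as per-position base-count matrices.

The pooled-plaque assay sequences the whole lacZ transgene as one amplicon, so
a sequencing library reduces to a per-position tally of base calls: for every
1-based position of the plus-strand reference we keep counts of A/C/G/T calls
(reads matching the reference are credited to the reference base), the total
aligned depth, and a dictionary of indel events keyed by their anchor position
and sequence.  The proportion of reads supporting a non-reference class at a
position is the basic observable from which mutations are called downstream.

Conventions
-----------
* Coordinates are 1-based on the plus strand of the lacZ reference.
* Strand case in the pileup string is collapsed (``a`` == ``A``): plaque pools
  carry no strand-specific information.
* Insertions (``+n<seq>``) are anchored at the base *preceding* the inserted
  sequence and keyed ``"+<SEQ>"``; deletions (``-n<seq>``) are anchored at the
  base preceding the deleted run and keyed ``"-<SEQ>"`` (so length and sequence
  both enter the event identity).  A ``*`` placeholder inside a deletion span
  contributes to depth only; the deletion event was already counted at its
  anchor.
* Base and mapping qualities are ignored (``^`` consumes its quality byte).
* Positions absent from the file (``mpileup`` without ``-a``) are zero-depth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: aggregate per-position event classes used for proportions and background
AGGREGATE_CLASSES = ("A", "C", "G", "T", "INS", "DEL")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class PileupError(ValueError):
    """Malformed pileup input (bad indel syntax, position order, ref mismatch)."""


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def aggregate_class(alt: str) -> str:
    """Collapse an event key to one of A/C/G/T/INS/DEL."""
    if alt.startswith("+"):
        return "INS"
    if alt.startswith("-"):
        return "DEL"
    if alt in _BASE_INDEX:
        return alt
    raise ValueError(f"not an event key: {alt!r}")


def load_reference(reference) -> str:
    """Return an upper-case reference sequence.

    Accepts a plain sequence string or a path to a single-record FASTA.
    """
    text = str(reference)
    if set(text.upper()) <= set("ACGTN") and not isinstance(reference, Path):
        return text.upper()
    from Bio import SeqIO

    records = list(SeqIO.parse(text, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


@dataclasses.dataclass(eq=False)
class BaseCountMatrix:
    """Per-position base-call counts for one sequencing library of one pool."""

    library_id: str
    reference: str
    base_counts: np.ndarray  # (L, 4) int, calls of A/C/G/T; ref matches credited to ref base
    depth: np.ndarray  # (L,) int, total aligned depth
    indels: dict  # {(pos, "+SEQ" | "-SEQ"): count}

    @classmethod
    def empty(cls, library_id: str, reference: str) -> "BaseCountMatrix":
        reference = reference.upper()
        L = len(reference)
        return cls(
            library_id=library_id,
            reference=reference,
            base_counts=np.zeros((L, 4), dtype=np.int64),
            depth=np.zeros(L, dtype=np.int64),
            indels={},
        )

    def __len__(self) -> int:
        return len(self.reference)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BaseCountMatrix):
            return NotImplemented
        return (
            self.reference == other.reference
            and np.array_equal(self.base_counts, other.base_counts)
            and np.array_equal(self.depth, other.depth)
            and self.indels == other.indels
        )

    def ref_base(self, pos: int) -> str:
        return self.reference[pos - 1]

    def indel_depth(self, kind: str) -> np.ndarray:
        """Total INS or DEL event count per position (length-L array)."""
        sign = {"INS": "+", "DEL": "-"}[kind]
        out = np.zeros(len(self), dtype=np.int64)
        for (pos, key), n in self.indels.items():
            if key.startswith(sign):
                out[pos - 1] += n
        return out

    def count(self, pos: int, alt: str) -> int:
        """Count for a keyed event: a base letter, '+SEQ' or '-SEQ'."""
        if alt in _BASE_INDEX:
            return int(self.base_counts[pos - 1, _BASE_INDEX[alt]])
        return int(self.indels.get((pos, alt), 0))

    def proportion(self, pos: int, alt: str) -> float:
        """count / depth for a keyed event; NaN where depth is zero."""
        d = self.depth[pos - 1]
        if d == 0:
            return float("nan")
        return self.count(pos, alt) / d

    def class_counts(self) -> np.ndarray:
        """(L, 6) counts for the aggregate classes A,C,G,T,INS,DEL."""
        out = np.zeros((len(self), 6), dtype=np.int64)
        out[:, :4] = self.base_counts
        out[:, 4] = self.indel_depth("INS")
        out[:, 5] = self.indel_depth("DEL")
        return out

    def event_keys(self):
        """Sorted candidate events: non-reference bases with count > 0, indels."""
        keys = []
        nz = np.nonzero(self.base_counts)
        for i, j in zip(*nz):
            base = BASES[j]
            if base != self.reference[i]:
                keys.append((int(i) + 1, base))
        keys.extend(k for k, n in self.indels.items() if n > 0)
        return sorted(keys)

    def validate(self) -> None:
        L = len(self.reference)
        if self.base_counts.shape != (L, 4) or self.depth.shape != (L,):
            raise ValueError("shape mismatch with reference length")
        if (self.base_counts < 0).any() or (self.depth < 0).any():
            raise ValueError("negative counts")
        if (self.base_counts.sum(axis=1) > self.depth).any():
            raise ValueError("base calls exceed depth")


def _decode_read_bases(s: str, line_no: int):
    """Decode one mpileup read-bases string.

    Returns (ref_match, {base: count}, n_other, {indel_key: count}) where
    n_other counts '*', N calls and reference skips (depth, no base call).
    """
    ref_match = 0
    bases: dict = {}
    other = 0
    indels: dict = {}
    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == "^":
            i += 2  # consume mapping-quality byte
        elif c == "$":
            i += 1
        elif c in ".,":
            ref_match += 1
            i += 1
        elif c in "ACGTacgt":
            b = c.upper()
            bases[b] = bases.get(b, 0) + 1
            i += 1
        elif c in "Nn":
            other += 1
            i += 1
        elif c in "*<>":
            other += 1
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and s[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupError(f"line {line_no}: malformed indel length after {c!r}")
            length = int(s[i + 1 : j])
            seq = s[j : j + length]
            if len(seq) < length or not set(seq.upper()) <= set("ACGTN"):
                raise PileupError(f"line {line_no}: malformed indel sequence {seq!r}")
            key = c + seq.upper()
            indels[key] = indels.get(key, 0) + 1
            i = j + length
        else:
            raise PileupError(f"line {line_no}: unexpected pileup character {c!r}")
    return ref_match, bases, other, indels


def parse_pileup(path, reference, library_id: str | None = None) -> BaseCountMatrix:
    """Parse mpileup text into a :class:`BaseCountMatrix`.

    Parameters
    ----------
    path : file path to 6-column mpileup text
    reference : plus-strand reference sequence (string) or FASTA path
    library_id : defaults to the file stem
    """
    ref = load_reference(reference)
    path = Path(path)
    m = BaseCountMatrix.empty(library_id or path.stem, ref)
    last_pos = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 5:
                raise PileupError(f"line {line_no}: expected >= 5 columns")
            pos = int(cols[1])
            if pos <= last_pos:
                raise PileupError(f"line {line_no}: positions out of order at {pos}")
            if pos > len(ref):
                raise PileupError(
                    f"line {line_no}: position {pos} beyond reference length {len(ref)}"
                )
            last_pos = pos
            ref_col = cols[2].upper()
            if ref_col not in ("N",) and ref_col != ref[pos - 1]:
                raise PileupError(
                    f"line {line_no}: reference base {ref_col} != FASTA {ref[pos - 1]}"
                )
            depth_col = int(cols[3])
            read_bases = cols[4] if depth_col > 0 else ""
            ref_match, bases, other, indels = _decode_read_bases(read_bases, line_no)
            tokens = ref_match + sum(bases.values()) + other
            if tokens != depth_col:
                raise PileupError(
                    f"line {line_no}: depth column {depth_col} != {tokens} decoded reads"
                )
            i = pos - 1
            m.depth[i] = tokens
            m.base_counts[i, _BASE_INDEX[ref[i]]] += ref_match
            for b, cnt in bases.items():
                m.base_counts[i, _BASE_INDEX[b]] += cnt
            for key, cnt in indels.items():
                m.indels[(pos, key)] = m.indels.get((pos, key), 0) + cnt
    m.validate()
    return m


def write_pileup(m: BaseCountMatrix, path, chrom: str = "lacZ") -> None:
    """Serialize a matrix to mpileup text (zero-depth positions are omitted).

    Indel events are attached to reference-matching or base-call reads at their
    anchor position, one event per read, matching how a parser re-counts them.
    """
    lines = []
    ins_by_pos: dict = {}
    for (pos, key), cnt in sorted(m.indels.items()):
        ins_by_pos.setdefault(pos, []).extend([key] * cnt)
    for i in range(len(m)):
        d = int(m.depth[i])
        if d == 0:
            continue
        pos = i + 1
        ref = m.reference[i]
        tokens = []
        for j, b in enumerate(BASES):
            c = int(m.base_counts[i, j])
            tokens.extend(["." if b == ref else b] * c)
        n_other = d - len(tokens)
        attachments = ins_by_pos.get(pos, [])
        if len(attachments) > len(tokens):
            raise PileupError(
                f"position {pos}: {len(attachments)} indel events but only "
                f"{len(tokens)} anchoring reads"
            )
        for k, key in enumerate(attachments):
            tokens[k] = tokens[k] + f"{key[0]}{len(key) - 1}{key[1:]}"
        tokens.extend(["*"] * n_other)
        lines.append(
            "\t".join([chrom, str(pos), ref, str(d), "".join(tokens), "I" * d])
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def alt_proportions(m: BaseCountMatrix) -> pd.DataFrame:
    """Tidy per-position proportions for every non-reference aggregate class.

    Rows are (position, alt_class, proportion) for the three non-reference
    bases plus INS and DEL at every covered position; zero-depth positions are
    omitted (missing, not zero).
    """
    cc = m.class_counts()
    rows = []
    ref_idx = np.array([_BASE_INDEX[b] for b in m.reference])
    for i in np.nonzero(m.depth > 0)[0]:
        d = m.depth[i]
        for j, cls in enumerate(AGGREGATE_CLASSES):
            if j == ref_idx[i]:
                continue
            rows.append((int(i) + 1, cls, cc[i, j] / d))
    return pd.DataFrame(rows, columns=["position", "alt_class", "proportion"])


def counts_frame(m: BaseCountMatrix) -> pd.DataFrame:
    """Base-count table: library_id, pos, ref, A, C, G, T, INS, DEL, depth."""
    cc = m.class_counts()
    return pd.DataFrame(
        {
            "library_id": m.library_id,
            "pos": np.arange(1, len(m) + 1),
            "ref": list(m.reference),
            "A": cc[:, 0],
            "C": cc[:, 1],
            "G": cc[:, 2],
            "T": cc[:, 3],
            "INS": cc[:, 4],
            "DEL": cc[:, 5],
            "depth": m.depth,
        }
    )
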