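"""Amplicon-read classification and the editing-efficiency statistic.

Reads are globally aligned to the wild-type and expected-edited
references and classified within a window around the cut site (default
+/-20 bp), so that sequencing errors far from the cut do not miscall
classes:

* ``edited`` — aligns to the edited reference with no gaps and no
  mismatches inside the window;
* ``wt`` — the same against the wild-type reference;
* ``indel`` — the best alignment places a gap inside the window;
* ``discarded`` — too short, below the outside-window identity floor,
  or carrying a window substitution matching neither reference (the
  last case is symmetric between edited- and wt-origin reads, so
  discarding it leaves the efficiency estimator unbiased).

Editing efficiency is the percentage of edited reads over total
retained (non-discarded) reads; the upstream read-filtering step of the
usual amplicon pipelines is what "total reads" is taken to mean here,
with discards reported separately.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, ParameterError

WINDOW_HALFWIDTH = 20


@dataclass(frozen=True)
class AmpliconRefs:
    """Wild-type and expected-edited reference sequences plus the
    classification window (half-open, in reference coordinates around
    the cut)."""

    wt: str
    edited: str
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.wt or not self.edited:
            raise EmptyInputError("references must be non-empty")
        if self.wt == self.edited:
            raise ParameterError("wt and edited references are identical")
        lo, hi = self.window
        if not (0 <= lo < hi <= len(self.wt)) or hi > len(self.edited):
            raise ParameterError(
                f"window [{lo}, {hi}) not contained in both references"
            )

    @classmethod
    def around_cut(
        cls,
        wt: str,
        edited: str,
        cut_position: int,
        halfwidth: int = WINDOW_HALFWIDTH,
    ) -> "AmpliconRefs":
        """Build refs with the window centred on a cut coordinate."""
        n = min(len(wt), len(edited))
        lo = max(0, cut_position - halfwidth)
        hi = min(n, cut_position + halfwidth)
        return cls(wt, edited, (lo, hi))


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds for read classification."""

    min_read_len: int = 50
    identity_floor: float = 0.8  # outside-window identity below which reads drop
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class AmpliconReport:
    """Per-class read counts and the editing-efficiency percentage."""

    edited: int = 0
    wt: int = 0
    indel: int = 0
    discarded: int = 0

    @property
    def total(self) -> int:
        return self.edited + self.wt + self.indel + self.discarded

    @property
    def retained(self) -> int:
        return self.total - self.discarded

    @property
    def efficiency_percent(self) -> float:
        return editing_efficiency(self.edited, self.wt, self.indel, self.discarded)

    def as_dict(self) -> dict:
        return {
            "edited": self.edited,
            "wt": self.wt,
            "indel": self.indel,
            "discarded": self.discarded,
            "total": self.total,
            "efficiency_percent": self.efficiency_percent,
        }


@dataclass(frozen=True)
class Alignment:
    """A global alignment: gapped strings plus the score."""

    a_aligned: str
    b_aligned: str
    score: int


def align_global(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment under a linear gap
    scheme, with a deterministic traceback preferring diagonal, then up
    (gap in ``b``), then left (gap in ``a``).

    The row recurrence is vectorized: with a linear gap penalty the
    within-row dependency ``H[i,j] = max(D[j], H[i,j-1]+g)`` unrolls to
    a running maximum, computed with ``np.maximum.accumulate``.
    """
    if not a or not b:
        raise EmptyInputError("align_global requires two non-empty sequences")
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    col = np.arange(m + 1, dtype=np.int64)
    H[0] = gap * col
    for i in range(1, n + 1):
        s = np.where(bv == av[i - 1], match, mismatch)
        D = np.empty(m + 1, dtype=np.int64)
        D[0] = gap * i
        np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap, out=D[1:])
        # H[i,j] = max_{k<=j} D[k] + gap*(j-k)
        H[i] = np.maximum.accumulate(D - gap * col) + gap * col

    a_out: list[str] = []
    b_out: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                a_out.append(a[i - 1])
                b_out.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            a_out.append(a[i - 1])
            b_out.append("-")
            i -= 1
            continue
        a_out.append("-")
        b_out.append(b[j - 1])
        j -= 1
    return Alignment("".join(reversed(a_out)), "".join(reversed(b_out)), int(H[n, m]))


@dataclass(frozen=True)
class _WindowStats:
    mismatches_in: int
    gaps_in: int
    outside_identity: float
    score: int


def _window_stats(aln: Alignment, window: tuple[int, int]) -> _WindowStats:
    """Walk an alignment (a = reference, b = read) and collect window
    mismatch/gap counts plus outside-window identity."""
    lo, hi = window
    ref_pos = 0
    mis_in = gaps_in = 0
    match_out = cols_out = 0
    for ra, rb in zip(aln.a_aligned, aln.b_aligned):
        in_window = lo <= ref_pos < hi
        if ra == "-" or rb == "-":
            if in_window:
                gaps_in += 1
            else:
                cols_out += 1
        elif ra != rb:
            if in_window:
                mis_in += 1
            else:
                cols_out += 1
        else:
            if not in_window:
                cols_out += 1
                match_out += 1
        if ra != "-":
            ref_pos += 1
    identity = match_out / cols_out if cols_out else 1.0
    return _WindowStats(mis_in, gaps_in, identity, aln.score)


def classify_read(
    read: str,
    refs: AmpliconRefs,
    params: ClassifyParams | None = None,
) -> str:
    """Assign one of ``edited | wt | indel | discarded`` to a read.

    Classification is a partition: every read receives exactly one
    label (``discarded`` is a class, not an error).
    """
    params = params or ClassifyParams()
    read = read.upper()
    if len(read) < params.min_read_len:
        return "discarded"
    aln_ed = align_global(refs.edited, read, params.match, params.mismatch, params.gap)
    aln_wt = align_global(refs.wt, read, params.match, params.mismatch, params.gap)
    st_ed = _window_stats(aln_ed, refs.window)
    st_wt = _window_stats(aln_wt, refs.window)
    best = st_ed if st_ed.score >= st_wt.score else st_wt
    if best.outside_identity < params.identity_floor:
        return "discarded"
    if st_ed.gaps_in == 0 and st_ed.mismatches_in == 0:
        return "edited"
    if st_wt.gaps_in == 0 and st_wt.mismatches_in == 0:
        return "wt"
    if best.gaps_in > 0:
        return "indel"
    return "discarded"


def editing_efficiency(edited: int, wt: int, indel: int, discarded: int = 0) -> float:
    """``100 * edited / (total - discarded)`` — the percentage of edited
    reads over total retained reads.  A zero denominator raises
    :class:`EmptyInputError`."""
    for name, v in (("edited", edited), ("wt", wt), ("indel", indel), ("discarded", discarded)):
        if v < 0:
            raise ParameterError(f"{name} count must be non-negative, got {v}")
    retained = edited + wt + indel
    if retained == 0:
        raise EmptyInputError("no retained reads; efficiency is undefined")
    return 100.0 * edited / retained


def quantify(
    reads: Iterable[str],
    refs: AmpliconRefs,
    params: ClassifyParams | None = None,
) -> AmpliconReport:
    """Classify every read and tally an :class:`AmpliconReport`."""
    params = params or ClassifyParams()
    report = AmpliconReport()
    for read in reads:
        label = classify_read(read, refs, params)
        setattr(report, label, getattr(report, label) + 1)
    return report


def read_fastq(path: str | Path, min_qual: float | None = None) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzip).

    Quality scores are read but unused unless ``min_qual`` is given, in
    which case reads whose mean Phred quality falls below it are
    skipped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            if min_qual is not None:
                quals = rec.letter_annotations["phred_quality"]
                if sum(quals) / len(quals) < min_qual:
                    continue
            yield str(rec.seq)
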