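"""Deterministic generators for test loci and simulated amplicon reads.

These fixtures emulate the two geometries the designs revolve around —
a locus with planted TTTV PAM(s) and a point mutation at a known
distance from the cut — and amplicon read sets drawn from a mixture of
wild-type, precisely edited and indel-bearing molecules with a per-base
substitution-error rate.

The generators are fully deterministic under a fixed seed (NumPy
``default_rng``, PCG64 — the algorithm is recorded in every manifest so
fixtures stay stable across releases).  Sequencing errors are
substitutions only; there is no simulated indel sequencing error, so
the ``indel`` class stays identifiable as planted indel reads
(documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import SimulationSpecError
from .nuclease_geometry import AS_CAS12A, NucleaseProfile, find_sites
from .outcome_quant import AmpliconRefs
from .seqcore import IUPAC_CODES, Locus, reverse_complement

RNG_ALGORITHM = "numpy.default_rng(PCG64)"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedPam:
    """A concrete PAM (e.g. ``TTTC``) planted at a top-strand start
    position; for ``-`` strand the reverse complement is written into
    the top strand and the protospacer extends to the left."""

    seq: str
    position: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantedMutation:
    """The locus carries ``mutant`` at ``position``; ``wild`` is the
    base a correction design would restore."""

    position: int
    mutant: str
    wild: str


@dataclass(frozen=True)
class LocusSpec:
    """Recipe for a reproducible synthetic locus.

    Invariants: planted features do not overlap and every PAM leaves
    room for a full protospacer.  After planting, accidental PAM sites
    elsewhere in the background are scrubbed so scans return exactly
    the planted sites.
    """

    seed: int
    length: int
    pams: tuple[PlantedPam, ...] = ()
    mutations: tuple[PlantedMutation, ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    name: str = "synthetic_locus"
    profile: NucleaseProfile = AS_CAS12A

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SimulationSpecError("locus length must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise SimulationSpecError("background weights must be >= 0 and sum to 1")
        iv: list[tuple[int, int]] = []
        span = len(self.profile.pam) + self.profile.protospacer_len
        for pam in self.pams:
            plen = len(pam.seq)
            if pam.strand == "+":
                lo, hi = pam.position, pam.position + span
            else:
                lo, hi = pam.position + plen - span, pam.position + plen
            if lo < 0 or hi > self.length:
                raise SimulationSpecError(
                    f"PAM at {pam.position} ({pam.strand}) leaves no room for a "
                    f"{self.profile.protospacer_len}-nt protospacer in {self.length} nt"
                )
            iv.append((pam.position, pam.position + plen))
        for mut in self.mutations:
            if not 0 <= mut.position < self.length:
                raise SimulationSpecError(f"mutation position {mut.position} outside locus")
            iv.append((mut.position, mut.position + 1))
        iv.sort()
        for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
            if a1 > b0:
                raise SimulationSpecError(
                    f"planted features overlap: [{a0},{a1}) and [{b0},{b1})"
                )


@dataclass(frozen=True)
class SyntheticLocus:
    """A generated locus plus its ground-truth manifest."""

    locus: Locus
    manifest: dict


def make_locus(spec: LocusSpec) -> SyntheticLocus:
    """Generate the locus described by ``spec``.

    The background is drawn from the base-composition weights, planted
    features are written in, and any accidental PAM site (with room for
    a protospacer, either strand) is destroyed by mutating an
    unprotected PAM base — so a scan returns exactly the planted sites.
    Same spec, same seed => bit-identical sequence.
    """
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(_BASES, size=spec.length, p=spec.background)
    protected: set[int] = set()
    for pam in spec.pams:
        written = pam.seq if pam.strand == "+" else reverse_complement(pam.seq)
        for k, base in enumerate(written):
            seq[pam.position + k] = ord(base)
        protected.update(range(pam.position, pam.position + len(pam.seq)))
    for mut in spec.mutations:
        seq[mut.position] = ord(mut.mutant)
        protected.add(mut.position)

    planted_keys = {
        ((p.position, p.position + len(p.seq)), p.strand) for p in spec.pams
    }
    for _ in range(200):
        locus = Locus(spec.name, seq.tobytes().decode("ascii"))
        accidental = [
            s
            for s in find_sites(locus, spec.profile)
            if (s.pam_interval, s.strand) not in planted_keys
        ]
        if not accidental:
            break
        changed = False
        for site in accidental:
            pam_lo, _ = site.pam_interval
            # PAM pattern as it reads on the top strand at this site
            pattern = (
                spec.profile.pam
                if site.strand == "+"
                else reverse_complement(spec.profile.pam)
            )
            # Prefer literal pattern positions (e.g. the T's of TTTV):
            # breaking those with a C cannot extend a homopolymer into a
            # fresh shifted PAM, which degenerate positions can.
            positions = sorted(
                (p for p in range(*site.pam_interval) if p not in protected),
                key=lambda p: len(IUPAC_CODES[pattern[p - pam_lo]]),
            )
            for pos in positions:
                allowed = IUPAC_CODES[pattern[pos - pam_lo]]
                breaker = next((b for b in "CGAT" if b not in allowed), None)
                if breaker is None:
                    continue
                seq[pos] = ord(breaker)
                changed = True
                break
        if not changed:
            raise SimulationSpecError(
                "cannot scrub accidental PAM sites: all positions protected"
            )
    else:
        raise SimulationSpecError("PAM scrubbing did not converge")

    manifest = {
        "name": spec.name,
        "seed": spec.seed,
        "length": spec.length,
        "rng": RNG_ALGORITHM,
        "pams": [
            {"seq": p.seq, "position": p.position, "strand": p.strand}
            for p in spec.pams
        ],
        "mutations": [
            {"position": m.position, "mutant": m.mutant, "wild": m.wild}
            for m in spec.mutations
        ],
    }
    return SyntheticLocus(locus=locus, manifest=manifest)


@dataclass(frozen=True)
class ReadSimSpec:
    """Recipe for a simulated amplicon read set.

    ``fractions`` gives the class mixture over ``edited | wt | indel``
    (must sum to 1 within 1e-9); ``error_rate`` is the per-base
    substitution probability (0-0.1); indel-class reads carry a
    ``indel_len``-bp deletion at the window centre.
    """

    refs: AmpliconRefs
    fractions: dict
    n_reads: int
    error_rate: float = 0.0
    read_len: int | None = None
    seed: int = 0
    indel_len: int = 2

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - {"edited", "wt", "indel"}
        if unknown:
            raise SimulationSpecError(f"unknown read classes: {sorted(unknown)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationSpecError(f"class fractions sum to {total}, expected 1")
        if min(self.fractions.values(), default=0.0) < 0:
            raise SimulationSpecError("class fractions must be non-negative")
        if not 0.0 <= self.error_rate <= 0.1:
            raise SimulationSpecError(
                f"error_rate must be in [0, 0.1], got {self.error_rate}"
            )
        if self.n_reads < 1:
            raise SimulationSpecError("n_reads must be positive")


def _class_reference(spec: ReadSimSpec, cls: str) -> str:
    if cls == "edited":
        return spec.refs.edited
    if cls == "wt":
        return spec.refs.wt
    lo, hi = spec.refs.window
    centre = (lo + hi) // 2
    wt = spec.refs.wt
    return wt[:centre] + wt[centre + spec.indel_len :]


def simulate_reads(spec: ReadSimSpec) -> list[SeqRecord]:
    """Draw ``n_reads`` reads from the class mixture (multinomial under
    the spec's seed) with independent per-base substitution errors.

    The class of origin is recorded in each read name
    (``read_<i>|class=<cls>``) for truth-aware tests.  With an all-
    edited mixture and zero error rate every read equals the edited
    reference.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ("edited", "wt", "indel")
    probs = [spec.fractions.get(c, 0.0) for c in classes]
    counts = rng.multinomial(spec.n_reads, probs)
    records: list[SeqRecord] = []
    idx = 0
    for cls, count in zip(classes, counts):
        ref = _class_reference(spec, cls)
        if spec.read_len is not None:
            ref = ref[: spec.read_len]
        base = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        for _ in range(count):
            read = base.copy()
            if spec.error_rate > 0:
                hits = np.nonzero(rng.random(len(read)) < spec.error_rate)[0]
                for pos in hits:
                    options = _BASES[_BASES != read[pos]]
                    read[pos] = rng.choice(options)
            seq = read.tobytes().decode("ascii")
            rec = SeqRecord(
                Seq(seq),
                id=f"read_{idx:06d}|class={cls}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [30] * len(seq)
            records.append(rec)
            idx += 1
    return records


def truth_class(record: SeqRecord) -> str:
    """Recover the class-of-origin label from a simulated read name."""
    return record.id.rsplit("class=", 1)[1]


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fastq")
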