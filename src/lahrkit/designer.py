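"""Repair-molecule construction and ranking.

Three template families are built here, all anchored on the staggered
Cas12a cut:

* **LAHR template** — a short dsDNA with (i) a 5' sticky end matching
  the PAM-distal genomic overhang, (ii) the correction carried on
  (iii) a homology arm covering the region adjacent to the PAM-proximal
  side of the break.  Ligation of the sticky end (resection-independent
  MMEJ) plus homologous recombination of the arm installs the edit.
* **CAPR insert** — dual cuts excise a genomic region; a dsDNA insert
  with one compatible 5' overhang at each end replaces it.
* **ssODN** — a conventional single-stranded HDR template spanning the
  nick, emitted on the non-target strand for Cas12a sites and on the
  target strand for Cas9 sites (the strand each nuclease prefers).

The arm is always on the PAM-proximal side and the sticky end always
targets the PAM-distal fragment; no mirrored variant is offered.
Scoring components are heuristics whose *directions* follow the
measured efficiency trends (arm-length optimum at 80 bp, penalties for
templates over ~120 bp, mutation-to-cut distance window 0-20 bp,
mid-arm extra mutations, re-cut protection from a single PAM-or-seed
disruption); their functional forms are package choices documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from .errors import (
    AnnotationError,
    DisruptionModeError,
    LigationIncompatibleError,
    NoSiteError,
    OrientationError,
    OverhangEditError,
    ParameterError,
    PlacementError,
)
from .nuclease_geometry import (
    AS_CAS12A,
    CutGeometry,
    NucleaseProfile,
    TargetSite,
    find_sites,
    mutation_cut_distance,
    staggered_cut,
)
from .seqcore import (
    Edit,
    Locus,
    apply_edits,
    iupac_matches,
    reverse_complement,
    synonymous_single_substitutions,
)

END_TYPES = ("matched", "5nt", "4nt", "3nt", "mismatched", "blunt", "3prime")

#: Linear taper width (bp) applied to the distance score beyond the window.
DISTANCE_TAPER = 20
#: Arm length below/above which the arm prior bottoms out.
ARM_MIN, ARM_OPT, ARM_MAX = 20, 80, 200
#: Floor value of the arm prior at its extremes.
ARM_FLOOR = 0.25
#: Total template length above which the length penalty engages; sizes
#: over ~100-120 bp diffuse poorly into the nucleus.
TOTAL_LEN_WARN = 120
#: Re-cut component without / with exactly one PAM-or-seed disruption.
RECUT_BASE, RECUT_DISRUPTED = 0.5, 1.0


@dataclass(frozen=True)
class DesignParams:
    """Tunable design constraints.

    Defaults encode the measured optima: 80-bp homology arm, 19th-base
    non-target nick (4-nt overhang), mutation-to-cut distance window of
    0-20 bp, and a 120-bp total-length warning threshold.  Disrupting
    *both* PAM and seed abolishes the re-cut-protection benefit, so
    ``disruption_mode`` admits only ``none | pam | seed``.
    """

    arm_len: int = 80
    nick_choice: int = 19
    end_type: str = "matched"
    distance_window: tuple[int, int] = (0, 20)
    total_len_warn: int = TOTAL_LEN_WARN
    disruption_mode: str = "none"
    extra_edit_positions: tuple[int, ...] = ()
    allow_overhang_edit: bool = False
    allow_noncoding_disruption: bool = False

    def __post_init__(self) -> None:
        if not ARM_MIN <= self.arm_len <= ARM_MAX:
            raise ParameterError(
                f"arm_len must be in [{ARM_MIN}, {ARM_MAX}], got {self.arm_len}"
            )
        if self.end_type not in END_TYPES:
            raise ParameterError(f"end_type must be one of {END_TYPES}, got {self.end_type!r}")
        lo, hi = self.distance_window
        if lo < 0 or hi < lo:
            raise ParameterError(f"bad distance window [{lo}, {hi}]")
        if self.disruption_mode not in ("none", "pam", "seed"):
            if "pam" in self.disruption_mode and "seed" in self.disruption_mode:
                raise DisruptionModeError(
                    "simultaneous PAM + seed disruption is not supported: the "
                    "editing-efficiency benefit of disrupting one is lost when "
                    "both are disrupted"
                )
            raise ParameterError(
                f"disruption_mode must be none|pam|seed, got {self.disruption_mode!r}"
            )


@dataclass(frozen=True)
class LahrTemplate:
    """A LAHR repair molecule.

    ``top_strand`` (5'->3') is the edited homology arm; ``bottom_strand``
    (5'->3') is its complement extended at the 5' end by ``overhang_seq``,
    the sticky end complementary to the PAM-distal genomic overhang.
    """

    top_strand: str
    bottom_strand: str
    overhang_seq: str
    arm_len: int
    edits_carried: tuple[Edit, ...]
    source_cut: CutGeometry
    end_type: str = "matched"
    arm_interval: tuple[int, int] = (0, 0)  # top-strand locus coords

    @property
    def total_len(self) -> int:
        """Length of the longer strand (arm + overhang)."""
        return max(len(self.top_strand), len(self.bottom_strand))


@dataclass(frozen=True)
class SsodnTemplate:
    """A single-stranded HDR template: ``left + right`` bases around the
    non-target-strand nick, carrying the edit."""

    seq: str
    strand_used: str  # "target" | "non-target"
    arms: tuple[int, int]
    nuclease: str
    edits_carried: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        if len(self.seq) != sum(self.arms):
            raise ParameterError(
                f"ssODN length {len(self.seq)} != left+right arms {sum(self.arms)}"
            )


@dataclass(frozen=True)
class CaprDesign:
    """A cut-and-paste design: two cuts and the double-sticky-ended
    insert replacing the excised region."""

    left_cut: CutGeometry
    right_cut: CutGeometry
    excised_interval: tuple[int, int]
    insert_top: str
    insert_bottom: str
    edits_carried: tuple[Edit, ...]
    replace_interval: tuple[int, int]
    replacement: str
    warnings: tuple[str, ...] = ()

    @property
    def left_overhang(self) -> str:
        """5' overhang at the insert's left end (on the top strand)."""
        a1 = self.left_cut.cut_top_strand
        a2 = self.left_cut.cut_bottom_strand
        return self.insert_top[: a2 - a1]

    @property
    def right_overhang(self) -> str:
        """5' overhang at the insert's right end (on the bottom strand)."""
        b1 = self.right_cut.cut_top_strand
        b2 = self.right_cut.cut_bottom_strand
        return self.insert_bottom[: b2 - b1]


@dataclass
class Candidate:
    """A scored design with per-component diagnostics.

    ``score`` is the product of the named components, each in [0, 1];
    candidates order by score descending, then top-strand coordinate
    ascending, then + strand before -.
    """

    template: LahrTemplate
    site: TargetSite
    cut: CutGeometry
    distance: int
    components: dict[str, float] = field(default_factory=dict)
    score: float = 0.0
    warnings: list[str] = field(default_factory=list)
    disruption_edit: Edit | None = None

    @property
    def sort_key(self) -> tuple[float, int, int]:
        return (-self.score, self.site.pam_interval[0], 0 if self.site.strand == "+" else 1)


@dataclass
class DesignReport:
    """Ranked candidates plus diagnostics for sites that were rejected.

    Behaves like the ranked candidate list.
    """

    candidates: list[Candidate]
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


# --------------------------------------------------------------------------
# Site-frame helpers.  Templates are constructed on the strand where the
# PAM + protospacer read 5'->3'; minus-strand inputs are mirrored in,
# results mirrored back where they refer to locus coordinates.

def _site_frame(locus: Locus, cut: CutGeometry) -> tuple[str, int, int]:
    """Return (site-frame sequence, non-target nick, target nick)."""
    n = len(locus.seq)
    if cut.site.strand == "+":
        return locus.seq, cut.nick_top, cut.nick_bottom
    return reverse_complement(locus.seq), n - cut.nick_top, n - cut.nick_bottom


def _to_site_frame_edit(edit: Edit, strand: str, n: int) -> Edit:
    return edit if strand == "+" else edit.mirrored(n)


def build_lahr_template(
    locus: Locus,
    cut: CutGeometry,
    edit: Edit | None,
    params: DesignParams | None = None,
    extra_edits: Sequence[Edit] = (),
    arm_len: int | None = None,
) -> LahrTemplate:
    """Construct the LAHR template for ``cut`` carrying ``edit``.

    The homology arm covers the ``arm_len`` bases immediately
    PAM-proximal of the non-target-strand nick; the bottom strand is
    extended by the reverse complement of the genomic overhang so that
    its 5' sticky end anneals to the PAM-distal fragment.  End-type
    variants alter only the sticky end: ``5nt``/``4nt``/``3nt`` take
    that many bases from the nick, ``mismatched`` complements the middle
    base of the matched overhang, ``blunt`` omits it, and ``3prime``
    moves the same bases to the top strand's 3' end (an approximation of
    the figure-only construction).

    Raises :class:`PlacementError` if the edit is outside the arm and
    :class:`OverhangEditError` if it falls inside the overhang without
    ``params.allow_overhang_edit``.
    """
    params = params or DesignParams()
    arm_len = params.arm_len if arm_len is None else arm_len
    if arm_len < 1:
        raise ParameterError(f"arm_len must be positive, got {arm_len}")
    n = len(locus.seq)
    sf_seq, c1, c2 = _site_frame(locus, cut)
    arm_lo = c1 - arm_len
    if arm_lo < 0:
        raise PlacementError(
            f"arm of {arm_len} bp extends past the sequence start "
            f"(nick at site-frame {c1})"
        )
    all_edits = ([edit] if edit is not None else []) + list(extra_edits)
    sf_edits = [_to_site_frame_edit(e, cut.site.strand, n) for e in all_edits]
    for e in sf_edits:
        lo, hi = e.interval
        if lo >= c1:
            if lo < c2 and not params.allow_overhang_edit:
                raise OverhangEditError(
                    f"edit at site-frame {lo} falls inside the overhang [{c1}, {c2}); "
                    "a mismatched sticky end lowers repair efficiency"
                )
            if lo >= c2:
                raise PlacementError(
                    f"edit at site-frame {lo} lies PAM-distal of the cut; "
                    "the homology arm cannot carry it"
                )
        elif lo < arm_lo:
            raise PlacementError(
                f"edit at site-frame {lo} outside the arm [{arm_lo}, {c1})"
            )
    edited_sf = apply_edits(sf_seq, sf_edits)
    arm = edited_sf[arm_lo:c1]
    genomic_overhang = edited_sf[c1:c2]

    et = params.end_type
    if et in ("matched", "4nt", "5nt", "3nt"):
        want = {"matched": c2 - c1, "4nt": 4, "5nt": 5, "3nt": 3}[et]
        ov = reverse_complement(edited_sf[c1 : c1 + want])
        top, bottom = arm, ov + reverse_complement(arm)
    elif et == "mismatched":
        ov = list(reverse_complement(genomic_overhang))
        mid = len(ov) // 2
        ov[mid] = reverse_complement(ov[mid])
        ov = "".join(ov)
        top, bottom = arm, ov + reverse_complement(arm)
    elif et == "blunt":
        ov = ""
        top, bottom = arm, reverse_complement(arm)
    elif et == "3prime":
        ov = genomic_overhang
        top, bottom = arm + ov, reverse_complement(arm)
    else:  # pragma: no cover - guarded by DesignParams validation
        raise ParameterError(f"unknown end_type {et!r}")

    if cut.site.strand == "+":
        arm_iv = (arm_lo, c1)
    else:
        arm_iv = (n - c1, n - arm_lo)
    return LahrTemplate(
        top_strand=top,
        bottom_strand=bottom,
        overhang_seq=ov,
        arm_len=arm_len,
        edits_carried=tuple(all_edits),
        source_cut=cut,
        end_type=et,
        arm_interval=arm_iv,
    )


def simulate_perfect_lahr(
    locus: Locus,
    cut: CutGeometry,
    template: LahrTemplate,
    strict: bool = True,
) -> str:
    """Idealized repair outcome: the arm interval replaced by the
    template arm and the sticky junction ligated to the PAM-distal
    fragment.  Serves as the design-correctness oracle: a template
    carrying edits yields exactly ``apply_edits(locus, edits)``.

    In strict mode a sticky end that is not perfectly complementary to
    the genomic overhang raises :class:`LigationIncompatibleError`.
    """
    n = len(locus.seq)
    sf_seq, c1, c2 = _site_frame(locus, cut)
    arm_len = len(template.top_strand) if template.end_type != "3prime" else len(template.top_strand) - len(template.overhang_seq)
    arm_lo = c1 - arm_len
    if strict:
        genomic_ov = sf_seq[c1:c2]
        if template.end_type == "3prime" or template.overhang_seq != reverse_complement(genomic_ov):
            raise LigationIncompatibleError(
                f"template sticky end {template.overhang_seq!r} is not complementary "
                f"to the genomic PAM-distal overhang {genomic_ov!r}"
            )
    arm = template.top_strand[:arm_len]
    repaired_sf = sf_seq[:arm_lo] + arm + sf_seq[c1:]
    return repaired_sf if cut.site.strand == "+" else reverse_complement(repaired_sf)


# --------------------------------------------------------------------------
# Codon-aware silent disruption of PAM or seed.

def _codon_at(locus: Locus, pos: int) -> tuple[str, int, tuple[int, int], str] | None:
    """Codon covering top-strand position ``pos``: (codon in coding
    orientation, offset of pos within it, top-strand interval, strand).
    None when the position is outside the CDS or its partial leading
    codon."""
    cds = locus.cds
    if cds is None or not (cds.start <= pos < cds.end):
        return None
    if cds.strand == "+":
        idx = pos - cds.start - cds.frame
        if idx < 0:
            return None
        ci, off = divmod(idx, 3)
        lo = cds.start + cds.frame + 3 * ci
        if lo + 3 > cds.end:
            return None
        return locus.seq[lo : lo + 3], off, (lo, lo + 3), "+"
    idx = (cds.end - 1 - pos) - cds.frame
    if idx < 0:
        return None
    ci, off = divmod(idx, 3)
    hi = cds.end - cds.frame - 3 * ci
    if hi - 3 < cds.start:
        return None
    codon = reverse_complement(locus.seq[hi - 3 : hi])
    return codon, off, (hi - 3, hi), "-"


def _seed_top_interval(site: TargetSite) -> tuple[int, int]:
    """Top-strand interval of the PAM-proximal seed region."""
    lo_off, hi_off = site.profile.seed_interval
    ps, pe = site.protospacer_interval
    if site.strand == "+":
        return (ps + lo_off, ps + hi_off)
    return (pe - hi_off, pe - lo_off)


def _pam_broken(locus: Locus, site: TargetSite, edit: Edit) -> bool:
    """Would applying ``edit`` break the site's PAM match?"""
    mutated = apply_edits(locus.seq, [edit])
    lo, hi = site.pam_interval
    pam_seq = mutated[lo:hi]
    if site.strand == "-":
        pam_seq = reverse_complement(pam_seq)
    return not iupac_matches(site.profile.pam, pam_seq)


def silent_disruption_candidates(
    locus: Locus,
    site: TargetSite,
    params: DesignParams,
) -> list[Edit]:
    """Single-base, codon-preserving substitutions that break the PAM
    (``disruption_mode='pam'``) or alter a seed base (``'seed'``).

    Disrupting the PAM or the seed prevents re-cutting of the repaired
    allele and raises editing efficiency; disrupting both at once loses
    the benefit, so only one mode may be requested.  Requires a CDS
    annotation covering the region unless
    ``params.allow_noncoding_disruption`` is set, in which case the
    codon-preservation constraint is waived (non-coding sequence).
    """
    mode = params.disruption_mode
    if mode == "none":
        return []
    if mode == "pam":
        region = site.pam_interval
    else:
        region = _seed_top_interval(site)

    out: list[Edit] = []
    coding_covered = locus.cds is not None and (
        locus.cds.start <= region[0] and region[1] <= locus.cds.end
    )
    if not coding_covered and not params.allow_noncoding_disruption:
        raise AnnotationError(
            f"{mode} region {region} is not covered by a CDS annotation; "
            "pass allow_noncoding_disruption to design without codon constraints"
        )
    for pos in range(*region):
        if coding_covered:
            info = _codon_at(locus, pos)
            if info is None:
                continue
            codon, _, codon_iv, cds_strand = info
            off = pos - codon_iv[0] if cds_strand == "+" else codon_iv[1] - 1 - pos
            for syn_off, alt in synonymous_single_substitutions(codon):
                if syn_off != off:
                    continue
                top_alt = alt if cds_strand == "+" else reverse_complement(alt)
                if top_alt == locus.seq[pos]:
                    continue
                cand = Edit(pos, locus.seq[pos], top_alt)
                if mode == "seed" or _pam_broken(locus, site, cand):
                    out.append(cand)
        else:
            for alt in "ACGT":
                if alt == locus.seq[pos]:
                    continue
                cand = Edit(pos, locus.seq[pos], alt)
                if mode == "seed" or _pam_broken(locus, site, cand):
                    out.append(cand)
    out.sort(key=lambda e: (e.position, e.alt))
    return out


# --------------------------------------------------------------------------
# ssODN and CAPR designs.

def design_ssodn(
    locus: Locus,
    edit: Edit,
    cut: CutGeometry,
    arms: tuple[int, int] = (50, 50),
) -> SsodnTemplate:
    """A single-stranded HDR template spanning ``left`` bases 5' of the
    non-target-strand nick through ``right`` bases 3' of it (site
    frame), with the edit applied.  Emitted on the non-target strand for
    Cas12a sites (the strand Cas12a-directed HDR prefers) and on the
    target strand for Cas9 sites.  Total length is always left+right:
    80/80 arms give a 160-nt ssODN, 50/50 a 100-nt one.
    """
    left, right = arms
    if left <= 0 or right <= 0:
        raise ParameterError(f"arm lengths must be positive, got {arms}")
    n = len(locus.seq)
    sf_seq, c1, _ = _site_frame(locus, cut)
    lo, hi = c1 - left, c1 + right
    if lo < 0 or hi > n:
        raise PlacementError(
            f"ssODN span [site-frame {lo}, {hi}) exceeds the locus (length {n})"
        )
    sf_edit = _to_site_frame_edit(edit, cut.site.strand, n)
    e_lo, e_hi = sf_edit.interval
    if e_lo < lo or e_hi > hi:
        raise PlacementError(
            f"edit at site-frame {e_lo} outside the ssODN span [{lo}, {hi})"
        )
    edited_sf = apply_edits(sf_seq, [sf_edit])
    span = edited_sf[lo:hi]
    if cut.site.profile.blunt:
        return SsodnTemplate(reverse_complement(span), "target", arms, cut.site.profile.name, (edit,))
    return SsodnTemplate(span, "non-target", arms, cut.site.profile.name, (edit,))


def design_capr(
    locus: Locus,
    replace_interval: tuple[int, int],
    replacement: str,
    params: DesignParams | None = None,
    strict: bool = False,
    profile: NucleaseProfile = AS_CAS12A,
) -> CaprDesign:
    """Design a cut-and-paste replacement: two Cas12a cuts flanking
    ``replace_interval`` and a dsDNA insert that reproduces the excised
    sequence with ``replacement`` applied, terminated by the two
    compatible 5' overhangs.

    The innermost qualifying cut pair (smallest excision) is chosen.
    Identical or mutually reverse-complementary overhangs cannot enforce
    insert orientation: that raises a warning, escalated to
    :class:`OrientationError` in strict mode.
    """
    params = params or DesignParams()
    rs, re_ = replace_interval
    if not (0 <= rs < re_ <= len(locus.seq)):
        raise ParameterError(f"bad replace interval [{rs}, {re_})")
    replacement = replacement.upper()
    cuts = [staggered_cut(s, params.nick_choice) for s in find_sites(locus, profile)]
    lefts = [c for c in cuts if c.cut_bottom_strand <= rs]
    rights = [c for c in cuts if c.cut_top_strand >= re_]
    if not lefts or not rights:
        raise NoSiteError(
            f"no Cas12a cut pair flanks [{rs}, {re_}): "
            f"{len(lefts)} usable on the left, {len(rights)} on the right"
        )
    left = max(lefts, key=lambda c: c.cut_top_strand)
    right = min(rights, key=lambda c: c.cut_bottom_strand)

    a1, a2 = left.cut_top_strand, left.cut_bottom_strand
    b1, b2 = right.cut_top_strand, right.cut_bottom_strand
    wt = locus.seq
    insert_top = wt[a1:rs] + replacement + wt[re_:b1]
    insert_bottom = reverse_complement(wt[a2:rs] + replacement + wt[re_:b2])

    warnings: list[str] = []
    lov, rov_bottom = wt[a1:a2], reverse_complement(wt[b1:b2])
    if lov == reverse_complement(rov_bottom) or lov == rov_bottom:
        msg = (
            f"insert overhangs {lov!r}/{rov_bottom!r} do not enforce orientation "
            "(identical or mutually reverse-complementary)"
        )
        if strict:
            raise OrientationError(msg)
        warnings.append(msg)

    excised = tuple(sorted((left.nick_top, right.nick_top)))
    return CaprDesign(
        left_cut=left,
        right_cut=right,
        excised_interval=excised,
        insert_top=insert_top,
        insert_bottom=insert_bottom,
        edits_carried=(),
        replace_interval=(rs, re_),
        replacement=replacement,
        warnings=tuple(warnings),
    )


def simulate_capr(locus: Locus, design: CaprDesign) -> str:
    """Ligate the insert into the doubly cut locus and return the
    resulting top strand; the round trip equals the intended replaced
    sequence exactly.  Non-complementary overhangs raise
    :class:`LigationIncompatibleError`."""
    wt = locus.seq
    a1, a2 = design.left_cut.cut_top_strand, design.left_cut.cut_bottom_strand
    b1, b2 = design.right_cut.cut_top_strand, design.right_cut.cut_bottom_strand
    if design.left_overhang != wt[a1:a2]:
        raise LigationIncompatibleError(
            f"insert left overhang {design.left_overhang!r} does not match the "
            f"genomic overhang {wt[a1:a2]!r}"
        )
    if design.right_overhang != reverse_complement(wt[b1:b2]):
        raise LigationIncompatibleError(
            f"insert right overhang {design.right_overhang!r} does not complement "
            f"the genomic overhang {wt[b1:b2]!r}"
        )
    return wt[:a1] + design.insert_top + wt[b1:]


# --------------------------------------------------------------------------
# Scoring and enumeration.

def _distance_component(d: int, window: tuple[int, int]) -> float:
    lo, hi = window
    if lo <= d <= hi:
        return 1.0
    over = (d - hi) if d > hi else (lo - d)
    return max(0.0, 1.0 - over / DISTANCE_TAPER)


def _arm_component(arm: int) -> float:
    if arm <= ARM_OPT:
        frac = (arm - ARM_MIN) / (ARM_OPT - ARM_MIN)
    else:
        frac = 1.0 - (arm - ARM_OPT) / (ARM_MAX - ARM_OPT)
    return ARM_FLOOR + (1.0 - ARM_FLOOR) * max(0.0, min(1.0, frac))


def _total_len_component(total: int, warn: int) -> float:
    if total <= warn:
        return 1.0
    return max(0.1, 1.0 - (total - warn) / 100.0)


def _mid_arm_component(cand: "Candidate") -> float:
    """Penalty for extra (silent) edits sitting far from the nick: their
    incorporation rate drops toward the blunt end of the arm."""
    cut = cand.cut
    extras = [e for e in cand.template.edits_carried[1:]]
    if cand.disruption_edit is not None and cand.disruption_edit not in extras:
        extras.append(cand.disruption_edit)
    if not extras:
        return 1.0
    worst = 0.0
    for e in extras:
        d = mutation_cut_distance(cut, e)
        frac = min(1.0, max(0.0, d / max(1, cand.template.arm_len - 1)))
        worst = max(worst, frac)
    return 1.0 - 0.5 * worst


def score_candidate(cand: Candidate, params: DesignParams) -> Candidate:
    """Fill in component scores and the product score.

    Components (each in [0, 1]): ``distance`` — maximal inside the 0-20
    bp window, linear taper beyond; ``arm`` — prior peaking at 80 bp;
    ``total_len`` — penalty above the 120-bp threshold; ``mid_arm`` —
    extra-edit placement penalty growing toward the blunt end;
    ``re_cut`` — boosted by exactly one PAM-or-seed disruption.
    """
    comps = {
        "distance": _distance_component(cand.distance, params.distance_window),
        "arm": _arm_component(cand.template.arm_len),
        "total_len": _total_len_component(cand.template.total_len, params.total_len_warn),
        "mid_arm": _mid_arm_component(cand),
        "re_cut": RECUT_DISRUPTED if cand.disruption_edit is not None else RECUT_BASE,
    }
    cand.components = comps
    score = 1.0
    for v in comps.values():
        score *= v
    cand.score = score
    if cand.template.total_len > params.total_len_warn:
        cand.warnings.append(
            f"total template length {cand.template.total_len} bp exceeds "
            f"{params.total_len_warn} bp; large templates transduce poorly"
        )
    return cand


def enumerate_designs(
    locus: Locus,
    edit: Edit,
    params: DesignParams | None = None,
    profile: NucleaseProfile = AS_CAS12A,
) -> DesignReport:
    """Score a LAHR candidate for every Cas12a site (both strands) whose
    geometry places the edit inside the homology arm and inside the
    mutation-to-cut distance window.  Deterministically ranked; an empty
    report carries a diagnostic per rejected site.
    """
    params = params or DesignParams()
    apply_edits(locus, [edit])  # ref check before any design
    report = DesignReport(candidates=[])
    for site in find_sites(locus, profile):
        cut = staggered_cut(site, params.nick_choice)
        d = mutation_cut_distance(cut, edit)
        lo, hi = params.distance_window
        label = f"site pam@{site.pam_interval[0]}({site.strand})"
        if d < lo or d > hi:
            report.diagnostics.append(
                f"{label}: mutation-to-cut distance {d} outside window [{lo}, {hi}]"
            )
            continue
        if d > params.arm_len - 1:
            report.diagnostics.append(
                f"{label}: edit {d} bp from the nick falls outside the {params.arm_len}-bp arm"
            )
            continue
        disruption: Edit | None = None
        extra: list[Edit] = []
        if params.disruption_mode != "none":
            try:
                options = silent_disruption_candidates(locus, site, params)
            except AnnotationError as exc:
                report.diagnostics.append(f"{label}: {exc}")
                options = []
            disruption = _pick_disruption(options, edit, cut, params)
            if disruption is not None:
                extra.append(disruption)
            else:
                report.diagnostics.append(
                    f"{label}: no usable codon-preserving {params.disruption_mode} disruption"
                )
        try:
            template = build_lahr_template(locus, cut, edit, params, extra_edits=extra)
        except (PlacementError, OverhangEditError) as exc:
            report.diagnostics.append(f"{label}: {exc}")
            continue
        cand = Candidate(
            template=template,
            site=site,
            cut=cut,
            distance=d,
            disruption_edit=disruption,
        )
        report.candidates.append(score_candidate(cand, params))
    report.candidates.sort(key=lambda c: c.sort_key)
    if not report.candidates and not report.diagnostics:
        report.diagnostics.append("no Cas12a site found on either strand")
    return report


def _pick_disruption(
    options: Sequence[Edit],
    correction: Edit,
    cut: CutGeometry,
    params: DesignParams,
) -> Edit | None:
    """First disruption edit >= 1 bp away from the correction and inside
    the arm (constraints reported per candidate by the caller)."""
    c_lo, c_hi = correction.interval
    for e in options:
        lo, hi = e.interval
        if hi > c_lo - 1 and lo < c_hi + 1:
            continue  # too close to (or overlapping) the correction
        d = mutation_cut_distance(cut, e)
        if 0 <= d <= params.arm_len - 1:
            return e
    return None


def template_to_oligos(template: LahrTemplate | CaprDesign) -> tuple[str, str]:
    """The exact pair of 5'->3' ssDNA strings to synthesize; annealing
    them reconstructs the duplex including its overhang(s).  A blunt
    template gives two exact reverse complements; a 4-nt 5'-overhang
    LAHR template a bottom oligo 4 nt longer than the top."""
    if isinstance(template, CaprDesign):
        return (template.insert_top, template.insert_bottom)
    return (template.top_strand, template.bottom_strand)
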