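"""Target-site scanning and staggered-cut geometry.

AsCas12a recognizes a T-rich PAM (TTTV) 5' of a ~23-nt protospacer and
cuts distally to the PAM with a single RuvC domain, nicking the
non-target strand after the 18th or 19th protospacer base and the
target strand after the 23rd, which leaves a 5-nt or 4-nt 5' overhang
respectively.  SpCas9 (NGG 3' of a 20-nt protospacer) cuts blunt 3 bp
5' of the PAM; that placement is a field convention, recorded here as
an assumption.

Coordinate frames
-----------------
Sites are located on both strands; all reported intervals are 0-based
half-open *top-strand* coordinates plus a strand flag.  The "site
frame" is the strand on which PAM + protospacer read 5'->3'; minus
sites are computed in their own frame and mirrored.  A cut position
``c`` means "between base c-1 and base c".
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import LigationIncompatibleError, ParameterError
from .seqcore import Edit, Locus, iupac_find, reverse_complement


@dataclass(frozen=True)
class NucleaseProfile:
    """PAM model and cut-geometry constants for one nuclease.

    ``nick_nontarget`` / ``nick_target`` count protospacer bases after
    the PAM (Cas12a) on the respective strand; the cut falls immediately
    3' of that base in the site frame.  The target-strand nick at the
    23rd base is the unique value consistent with the 18th/19th-base
    non-target nicks and 5/4-nt overhangs; it is derived rather than
    measured, so it stays configurable.  The seed is the PAM-proximal
    protospacer stretch most sensitive to mismatches; its extent
    (default bases 1-6) is likewise configurable.
    """

    name: str
    pam: str
    pam_side: str  # "5prime" (Cas12a) or "3prime" (Cas9)
    protospacer_len: int
    nick_nontarget: int
    nick_target: int
    nick_choices: tuple[int, ...]
    seed_interval: tuple[int, int] = (0, 6)  # protospacer offsets, half-open
    spacer_len: int = 21
    blunt: bool = False

    def __post_init__(self) -> None:
        if self.pam_side not in ("5prime", "3prime"):
            raise ParameterError(f"pam_side must be 5prime/3prime, got {self.pam_side!r}")
        if self.nick_nontarget not in self.nick_choices:
            raise ParameterError(
                f"default nick {self.nick_nontarget} not in allowed {self.nick_choices}"
            )
        if not self.blunt and self.nick_target < self.nick_nontarget:
            raise ParameterError("target-strand nick must not precede the non-target nick")
        if not 18 <= self.spacer_len <= 25:
            raise ParameterError(f"spacer_len must be in [18, 25], got {self.spacer_len}")

    @property
    def overhang_len(self) -> int:
        return 0 if self.blunt else self.nick_target - self.nick_nontarget


def as_cas12a(
    *,
    nick_nontarget: int = 19,
    nick_target: int = 23,
    spacer_len: int = 21,
    seed_interval: tuple[int, int] = (0, 6),
) -> NucleaseProfile:
    """AsCas12a profile: TTTV PAM 5' of a 23-nt protospacer.

    The default non-target nick is the 19th base (4-nt overhang), the
    variant whose template sticky end perfectly matches the PAM-distal
    genomic end and gave the highest repair efficiency.
    """
    return NucleaseProfile(
        name="AsCas12a",
        pam="TTTV",
        pam_side="5prime",
        protospacer_len=23,
        nick_nontarget=nick_nontarget,
        nick_target=nick_target,
        nick_choices=(18, 19),
        seed_interval=seed_interval,
        spacer_len=spacer_len,
    )


def sp_cas9(*, spacer_len: int = 20) -> NucleaseProfile:
    """SpCas9 profile: NGG PAM 3' of a 20-nt protospacer, blunt cut
    after protospacer base 17 (3 bp 5' of the PAM)."""
    return NucleaseProfile(
        name="SpCas9",
        pam="NGG",
        pam_side="3prime",
        protospacer_len=20,
        nick_nontarget=17,
        nick_target=17,
        nick_choices=(17,),
        spacer_len=spacer_len,
        blunt=True,
    )


AS_CAS12A = as_cas12a()
SP_CAS9 = sp_cas9()


@dataclass(frozen=True)
class TargetSite:
    """A located PAM + protospacer.

    ``strand`` is the strand on which PAM and protospacer read 5'->3';
    intervals are top-strand 0-based half-open.  ``protospacer_seq`` is
    the protospacer in the site frame (identical to the non-target
    strand sequence) and ``spacer_seq`` the crRNA spacer: its
    PAM-proximal ``spacer_len`` bases.
    """

    profile: NucleaseProfile
    locus_name: str
    strand: str
    pam_interval: tuple[int, int]
    protospacer_interval: tuple[int, int]
    protospacer_seq: str
    spacer_seq: str

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.pam_interval[0], 0 if self.strand == "+" else 1)


@dataclass(frozen=True)
class CutGeometry:
    """The two nick positions of one cut, in top-strand coordinates.

    ``nick_top`` is the non-target-strand nick and ``nick_bottom`` the
    target-strand nick, both mirrored into top-strand coordinates for
    minus-strand sites (so ``nick_bottom < nick_top`` there).
    ``overhang_seq`` holds the 5'-overhang bases as they read on the
    site's non-target strand — exactly the protospacer bases strictly
    between the two nicks.
    """

    site: TargetSite
    nick_top: int
    nick_bottom: int
    overhang_seq: str
    overhang_len: int
    nick_choice: int

    @property
    def overhang_interval(self) -> tuple[int, int]:
        """Top-strand half-open interval of the single-stranded overhang."""
        lo, hi = sorted((self.nick_top, self.nick_bottom))
        return (lo, hi)

    @property
    def cut_top_strand(self) -> int:
        """Top-strand coordinate where the top strand is severed.

        A 5' overhang always puts the top-strand cut at the left edge of
        the overhang interval, whichever strand hosts the site.
        """
        return self.overhang_interval[0]

    @property
    def cut_bottom_strand(self) -> int:
        """Top-strand coordinate where the bottom strand is severed."""
        return self.overhang_interval[1]


def find_sites(locus: Locus, profile: NucleaseProfile = AS_CAS12A) -> list[TargetSite]:
    """All target sites of ``profile`` on both strands of ``locus``,
    sorted by top-strand PAM start, then + before -.

    Sites whose protospacer would run off the sequence are excluded.
    An empty list is a valid result.
    """
    n = len(locus.seq)
    plen = len(profile.pam)
    sites: list[TargetSite] = []
    for strand, seq in (("+", locus.seq), ("-", reverse_complement(locus.seq))):
        for p in iupac_find(profile.pam, seq):
            if profile.pam_side == "5prime":
                ps, pe = p + plen, p + plen + profile.protospacer_len
            else:
                ps, pe = p - profile.protospacer_len, p
            if ps < 0 or pe > n:
                continue  # protospacer runs off the sequence
            proto = seq[ps:pe]
            if profile.pam_side == "5prime":
                spacer = proto[: profile.spacer_len]
            else:
                spacer = proto[-profile.spacer_len :]
            if strand == "+":
                pam_iv, proto_iv = (p, p + plen), (ps, pe)
            else:
                pam_iv, proto_iv = (n - p - plen, n - p), (n - pe, n - ps)
            sites.append(
                TargetSite(
                    profile=profile,
                    locus_name=locus.name,
                    strand=strand,
                    pam_interval=pam_iv,
                    protospacer_interval=proto_iv,
                    protospacer_seq=proto,
                    spacer_seq=spacer,
                )
            )
    sites.sort(key=lambda s: s.sort_key)
    return sites


def staggered_cut(site: TargetSite, nick_nontarget_choice: int | None = None) -> CutGeometry:
    """Place the two nicks for ``site`` and report the 5' overhang.

    For Cas12a the non-target strand is nicked after the chosen base
    (18 -> 5-nt overhang, 19 -> 4-nt) and the target strand after the
    profile's ``nick_target`` base.  A Cas9 site yields a blunt geometry
    (overhang length 0).  A nick choice outside the profile's allowed
    set raises :class:`ParameterError`.
    """
    prof = site.profile
    choice = prof.nick_nontarget if nick_nontarget_choice is None else nick_nontarget_choice
    if choice not in prof.nick_choices:
        raise ParameterError(
            f"nick choice {choice} not allowed for {prof.name}; allowed: {prof.nick_choices}"
        )
    nt_sf = choice
    t_sf = choice if prof.blunt else prof.nick_target
    ps, pe = site.protospacer_interval
    if site.strand == "+":
        nick_top, nick_bottom = ps + nt_sf, ps + t_sf
    else:
        nick_top, nick_bottom = pe - nt_sf, pe - t_sf
    lo_sf, hi_sf = sorted((nt_sf, t_sf))
    overhang = site.protospacer_seq[lo_sf:hi_sf]
    return CutGeometry(
        site=site,
        nick_top=nick_top,
        nick_bottom=nick_bottom,
        overhang_seq=overhang,
        overhang_len=len(overhang),
        nick_choice=choice,
    )


def mutation_cut_distance(cut: CutGeometry, edit: Edit) -> int:
    """Signed distance (bp) between an edit and the non-target-strand
    nick: the number of bases strictly between the edited base and the
    nick, positive when the nick lies PAM-distal (downstream) of the
    edit in the site's frame.

    A point mutation at the 14th protospacer base combined with the
    18th-base nick is therefore +4 (the nick is 4 bp downstream of the
    mutation).  An edit inside or beyond the overhang gives a negative
    distance.  Multi-base edits report the affected base nearest the
    nick.
    """
    dists = []
    for pos in range(*edit.interval):
        if cut.site.strand == "+":
            d = cut.nick_top - pos - 1
        else:
            d = pos - cut.nick_top
        dists.append(d)
    return min(dists, key=abs)


# --------------------------------------------------------------------------
# Fragmenting and rejoining molecules.

@dataclass(frozen=True)
class DuplexFragment:
    """One double-stranded fragment of a cut locus.

    ``top`` / ``bottom`` are the half-open top-strand intervals covered
    by the respective strands; a 5' overhang exists wherever one strand
    extends past the other.  Strand sequences read 5'->3'.
    """

    top: tuple[int, int]
    bottom: tuple[int, int]
    top_seq: str
    bottom_seq: str


def cut_fragments(locus: Locus, cut: CutGeometry) -> tuple[DuplexFragment, DuplexFragment]:
    """Sever ``locus`` at ``cut``, returning (left, right) fragments.

    The left fragment carries a bottom-strand 5' overhang over the
    overhang interval, the right fragment the complementary top-strand
    5' overhang — the two sticky ends re-anneal to restore the locus.
    """
    a, b = cut.overhang_interval
    seq = locus.seq
    n = len(seq)
    left = DuplexFragment((0, a), (0, b), seq[:a], reverse_complement(seq[:b]))
    right = DuplexFragment((a, n), (b, n), seq[a:], reverse_complement(seq[b:]))
    return left, right


def rejoin(left: DuplexFragment, right: DuplexFragment) -> str:
    """Anneal and ligate two fragments' complementary 5' overhangs,
    returning the top strand of the rejoined duplex.

    Raises :class:`LigationIncompatibleError` when the sticky ends do
    not base-pair.
    """
    ov_left = left.bottom[1] - left.top[1]
    ov_right = right.bottom[0] - right.top[0]
    if ov_left != ov_right:
        raise LigationIncompatibleError(
            f"overhang lengths differ: {ov_left} vs {ov_right}"
        )
    left_ov = left.bottom_seq[:ov_left] if ov_left else ""
    right_ov = right.top_seq[:ov_right] if ov_right else ""
    if reverse_complement(left_ov) != right_ov:
        raise LigationIncompatibleError(
            f"sticky ends not complementary: {left_ov!r} vs {right_ov!r}"
        )
    return left.top_seq + right.top_seq
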