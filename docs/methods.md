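# Methods

## Cut model

AsCas12a is modelled by a `NucleaseProfile`: TTTV PAM 5′ of a 23-nt
protospacer, non-target-strand nick after the 18th or 19th protospacer
base, target-strand nick after the 23rd. The published description of
the enzyme fixes the non-target nick positions and the resulting
5-nt/4-nt 5′ overhangs; the target-strand nick at base 23 is the unique
value consistent with both, so it is a **derived constant and remains a
profile parameter** rather than a hard-coded fact. The default
non-target nick is 19 (4-nt overhang) because the perfectly matched
4-nt template end repairs best. SpCas9 is carried along for ssODN
comparisons as a blunt cutter 3 bp 5′ of NGG — a field convention, not
something this package's data establishes.

All coordinates are 0-based half-open on the locus top strand; a cut
position `c` means "between base `c−1` and base `c`". Minus-strand
sites are computed in their own frame (where PAM + protospacer read
5′→3′) and mirrored. For any Cas12a site, on the top strand the
top-strand cut lies left of the bottom-strand cut, so the right
fragment always carries a top-strand 5′ overhang and the left fragment
the complementary bottom-strand one; `cut_fragments`/`rejoin` encode
this and the rejoining round trip is property-tested.

The **mutation-to-cut distance** is the number of bases strictly
between the edited base and the non-target nick, positive when the
nick is PAM-distal of the edit. This convention makes the worked
endogenous-gene case — PAM 14 bp upstream of the mutation, 18th-base
nick — come out as +4, matching how that geometry is described
(14 + 4 = 18). The "14 bp upstream" reading (PAM 3′ end to mutation)
is inferred from that internal consistency and used only here.

## Template construction

The homology arm is always PAM-proximal and the sticky end always
targets the PAM-distal fragment; no mirrored variant is offered
because the underlying efficiency data never tests one. Edits inside
the overhang are rejected by default (a mismatched sticky end lowers
efficiency); `allow_overhang_edit` overrides. `simulate_perfect_lahr`
is the design-correctness oracle: the idealized repair product must
equal `apply_edits(locus, edits)` exactly, and in strict mode any
sticky end not perfectly complementary to the genomic overhang refuses
to ligate.

End-type variants mirror the experimental template series but their
exact construction is figure-only, so they are implemented as the
simplest consistent molecules and marked approximate: `5nt/4nt/3nt`
take that many bases starting at the non-target nick, `mismatched`
complements the middle base of the matched overhang, `blunt` omits it,
and `3prime` moves the same bases to the top strand's 3′ end.

CAPR inserts reproduce the genomic sequence between the two strand
cuts with the replacement applied, terminated by the two flank-
complementary 5′ overhangs. When several cut pairs flank the
replacement the **innermost pair** (smallest excision) is chosen, ties
leftmost — smallest perturbation, deterministic output. Identical or
mutually reverse-complementary overhangs cannot enforce insert
orientation (the flanks could also re-close directly); this warns, or
errors in strict mode.

ssODN arms are measured from the non-target nick with the edit
contained in whichever arm covers it, which makes 80/80 → 160 nt and
50/50 → 100 nt exact. Cas12a ssODNs are emitted on the non-target
strand and Cas9 ssODNs on the target strand, the documented strand
preferences.

## Scoring

`score = Π components`, each in [0, 1]. Only the *directions* of the
components come from measured efficiency trends; the functional forms
are deliberately simple package heuristics:

| component | form | default-relevant constants |
|---|---|---|
| `distance` | 1 inside the window, linear taper beyond | window [0, 20] bp, taper 20 bp |
| `arm` | triangular prior peaking at 80 bp, floor 0.25 at 20/200 bp | optimum 80 bp |
| `total_len` | 1 up to the threshold, then linear to a 0.1 floor | threshold 120 bp |
| `mid_arm` | 1 − 0.5 × (fractional distance of the farthest extra edit from the nick) | — |
| `re_cut` | 0.5 without, 1.0 with exactly one PAM-or-seed disruption | — |

The total-length threshold is 120 bp (the experimentally stated
drop-off); a stricter "over 100 bp" caution also appears in the
source data's discussion and is noted here rather than encoded.
Scores are **relative ranks only** — the package predicts no absolute
editing efficiency.

## Codon-aware disruption

Silent disruptions are single-base substitutions that preserve the
encoded amino acid (standard genetic code only) and either break the
TTTV match (`pam` mode) or alter a base in the PAM-proximal seed
(default protospacer bases 1–6; the seed's extent is not precisely
defined, so it is configurable). Requesting both modes at once is
unrepresentable, because disrupting both PAM and seed loses the
re-cut-protection benefit. Without a covering CDS the operation
refuses unless `allow_noncoding_disruption` waives the codon
constraint.

A consequence of third-position T↔C equivalence in the standard code:
for a plus-strand CDS fully covering the PAM, exactly one of the three
PAM T's always falls on a codon wobble position, so a synonymous
PAM-breaking T→C **always exists** (property-tested). Empty candidate
lists therefore arise only for seed mode (e.g. a seed spanned by
Met/Trp codons), partial CDS coverage, or minus-strand frames.

## Outcome quantification

Reads are aligned to both references with a hand-rolled
Needleman–Wunsch (match +1, mismatch −1, linear gap −2) with a
deterministic diagonal > up > left traceback; the row recurrence is
vectorized with a running-maximum identity, and the aligner is checked
against an exhaustive alignment-enumeration oracle in the tests.
Classification is windowed (±20 bp around the cut) so errors far from
the cut cannot miscall a class: `edited`/`wt` require a gap-free,
mismatch-free window against the respective reference, a windowed gap
in the best alignment gives `indel`, and reads below the
outside-window identity floor (80%) are `discarded`.

"Total reads" in the efficiency formula is taken as total *retained*
reads — upstream amplicon pipelines filter before quantifying — with
discards reported separately. A read whose window carries a
substitution matching neither reference (a sequencing error at a
non-edit position, no gap) is also discarded: such errors strike
edited- and wild-type-origin reads at the same per-base rate, so
removing them leaves the `edited/(total − discarded)` estimator
unbiased; the parameter-recovery test verifies this at a planted 25%
fraction, n = 1000 reads, 0.5% error.

## Synthetic fixtures

`make_locus` draws a background from base-composition weights (default
uniform), writes in the planted PAMs/mutations, and then scrubs
accidental PAM sites so a scan returns exactly the planted geometry —
scrubbing prefers literal pattern positions (the T's) broken with a C,
because breaking a degenerate position can extend a homopolymer into a
fresh shifted PAM. RNG is NumPy `default_rng` (PCG64), recorded in
every manifest; same spec + seed gives bit-identical output.

`simulate_reads` draws class counts from a multinomial over
`edited/wt/indel` and applies independent per-base substitution
errors. What this emulates: an amplicon sequencing run over a clonal
mixture with uniform substitution noise. What it does not: quality-
dependent or homopolymer error profiles, indel sequencing errors
(substitution-only by design, so the `indel` class stays identifiable
as planted 2-bp deletions at the window centre), PCR duplicates, or
paired-end structure. Passing tests therefore demonstrate correctness
of the classification logic and estimator, not robustness to real
sequencer artefacts.

## Problem sizes and numerical choices

Property suites run on deliberately small problems chosen as
representative rather than exhaustive: 1000 randomized 160-nt loci for
the LAHR round trip, 50 fixtures each for CAPR and mirror symmetry,
200 random sequences for the scan oracle, read sets of 1000 reads with
~116-nt references for recovery. Ranking ties break by score
descending, then top-strand coordinate ascending, then + before −, so
output order is total and reproducible. Degenerate inputs (empty
sequences, zero retained reads, edits overlapping the overhang,
infeasible fixture specs) raise typed errors from `lahrkit.errors`
rather than producing silent defaults.

## Known limitations

No off-target search, no thermodynamic or chromatin-based guide
scoring, no absolute efficiency prediction, no chemical-modification
planning for oligos, single-end reads only, standard genetic code
only. Whether a homology arm may extend 5′ of the PAM is left allowed
(long arms necessarily do), but its interaction with re-cutting is
untested in the underlying data.
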