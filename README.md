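# lahrkit

A design toolkit for **Cas12a sticky-end genome editing**. AsCas12a
recognizes a T-rich PAM (TTTV) and cuts with a stagger, nicking the
non-target strand at the 18th or 19th base behind the PAM and the
target strand at the 23rd, leaving a 5-nt or 4-nt 5′ overhang. A short
double-stranded repair template that carries (i) a sticky end
complementary to the PAM-distal genomic overhang and (ii) a homology
arm covering the PAM-proximal side of the break can then install a
point mutation through a combination of resection-independent MMEJ
(ligation of the sticky end) and HDR (recombination of the arm) —
*ligation-assisted homologous recombination* (LAHR). Two cuts plus a
double-sticky-ended insert give *cut-and-paste* replacement of a whole
region (CAPR).

`lahrkit` is for anyone designing these experiments: it scans loci for
TTTV (and NGG) sites on both strands, models the staggered cut, builds
LAHR templates / CAPR inserts / comparison ssODNs under empirically
motivated constraints, emits orderable oligos and crRNA spacers, and
quantifies editing outcomes from amplicon reads.

## The model

For a site with PAM at positions `p..p+4` (site strand) and a 23-nt
protospacer, the non-target strand is nicked after protospacer base
`c ∈ {18, 19}` and the target strand after base 23, so the 5′ overhang
is protospacer bases `(c, 23]` — 5 nt for `c = 18`, 4 nt for `c = 19`
(the default: a template whose sticky end perfectly matches the 4-nt
PAM-distal overhang repairs best). The LAHR template for a cut is

```
top    5'-[ homology arm, arm_len bp, carrying the edit ]-3'
bottom 3'-[ complement of arm ]-[ 5' overhang = revcomp(genomic overhang) ]-5'
```

Candidate designs are ranked by a product of `[0, 1]` components whose
directions follow the measured efficiency trends: mutation-to-cut
distance (flat within 0–20 bp, tapering beyond), an arm-length prior
peaking at 80 bp, a total-length penalty above 120 bp, a mid-arm
placement penalty for extra silent mutations, and a re-cut-protection
bonus for exactly one codon-preserving PAM *or* seed disruption
(disrupting both loses the benefit and is unrepresentable).

Editing outcomes are quantified from FASTQ reads by global alignment
(Needleman–Wunsch, match +1 / mismatch −1 / gap −2, deterministic
traceback) against the wild-type and expected-edited references inside
a ±20 bp window around the cut, and

```
efficiency (%) = 100 × edited reads / (total − discarded) reads.
```

## Worked example

Generate a deterministic 200-nt locus with one planted TTTC PAM at
position 100, then design a repair for a substitution 2 bp from the
nick:

```sh
lahrkit simulate-locus --seed 42 --length 200 --pam TTTC:100:+ --out-prefix demo
lahrkit design demo.fasta --edit "121:G>A"
```

The JSON report contains one candidate:

```
score       = 0.5
components  = {distance: 1.0, arm: 1.0, total_len: 1.0, mid_arm: 1.0, re_cut: 0.5}
strand      = +         distance_bp = 2
spacer      = TGCCATCACGATTGCGGGACA
overhang    = GGTG
top_oligo    (80 nt) = CTTCCGCAATGGTCGAAGCGTGGGCACACTAACCGGTGCTCAAGCAGAGCCCGCAATTTTCTGCCATCACGATTGCGAGA
bottom_oligo (84 nt) = GGTGTCTCGCAATCGTGATGGCAGAAAATTGCGGGCTCTGCTTGAGCACCGGTTAGTGTGCCCACGCTTCGACCATTGCGGAAG
```

Reading this: the edit sits 2 bp from the 19th-base nick (inside the
favourable 0–20 bp window, so `distance = 1.0`), the arm is the optimal
80 bp, and the bottom oligo is 4 nt longer than the top — its 5′
`GGTG` is the sticky end, the reverse complement of the genomic
PAM-distal overhang `CACC`. The `re_cut` component is 0.5 because no
PAM/seed disruption was requested (`--disrupt pam` adds one when the
locus has a CDS annotation). Annealing the two oligos yields the
orderable template; `spacer` is the 21-nt crRNA spacer for the site.

A comparison 100-nt ssODN for the same edit
(`lahrkit ssodn demo.fasta --edit "121:G>A" --arms 50,50`) is emitted
on the non-target strand — the strand Cas12a-directed HDR prefers —
with `length = 100 = 50 + 50`.

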