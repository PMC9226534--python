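"""Shared fixtures: small hand-constructed loci with known Cas12a
geometry, plus hypothesis configuration (derandomized for reproducible
CI runs)."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from lahrkit import Edit, Locus, find_sites, staggered_cut
from lahrkit.seqcore import CdsAnnotation

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: 23-nt protospacer used throughout; bases 20-23 are CAAT, so the
#: 19th-base nick yields overhang "CAAT" and the 18th-base nick "GCAAT".
PROTOSPACER = "ACTGAACCTTGGAACCTTGCAAT"


@pytest.fixture
def single_site_locus() -> Locus:
    """35-nt locus with exactly one Cas12a site: GCAG + TTTC +
    protospacer + GCAG (flanks chosen so the bottom strand carries no
    accidental TTTV)."""
    return Locus("single", "GCAG" + "TTTC" + PROTOSPACER + "GCAG")


@pytest.fixture
def single_site(single_site_locus):
    sites = find_sites(single_site_locus)
    assert len(sites) == 1
    return sites[0]


@pytest.fixture
def design_locus() -> Locus:
    """200-nt locus with one plus-strand TTTC PAM at 100, CDS covering
    the whole sequence, leaving >=80 bp on the PAM-proximal side of the
    nick so default-length arms fit."""
    import numpy as np

    from lahrkit import LocusSpec, PlantedPam, make_locus

    built = make_locus(LocusSpec(seed=42, length=200, pams=(PlantedPam("TTTC", 100, "+"),)))
    return Locus(built.locus.name, built.locus.seq, CdsAnnotation(0, 198, "+", 0))


@pytest.fixture
def design_cut(design_locus):
    (site,) = find_sites(design_locus)
    return staggered_cut(site, 19)


def correction_edit(locus: Locus, position: int) -> Edit:
    """A substitution edit at ``position`` differing from the locus."""
    ref = locus.seq[position]
    alt = "A" if ref != "A" else "G"
    return Edit(position, ref, alt)
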