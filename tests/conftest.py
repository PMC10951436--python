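import edlib
import pytest

from tylocus import sim, util


@pytest.fixture(scope="session")
def library():
    return sim.default_library()


@pytest.fixture(scope="session")
def trnas():
    return sim.default_trnas()


@pytest.fixture(scope="session")
def root_locus(library):
    """Ancestral haplotype + truth from the default relic-like blueprint."""
    bp = sim.relic_blueprint()
    return sim.build_locus_haplotype(bp, library, flank_len=5000, seed=1)


@pytest.fixture(scope="session")
def panel(library):
    """The default 20-strain simulated panel (truth only, no reads)."""
    strains, lib, nwk = sim.build_panel(seed=3)
    return strains, nwk


def identity_to(contig: str, truth: str) -> float:
    """Errors per aligned contig base, orientation-normalized (infix)."""
    best = min(edlib.align(contig, t, mode="HW")["editDistance"]
               for t in (truth, util.revcomp(truth)))
    return 1.0 - best / len(contig)


def nw_distance(a: str, b: str) -> int:
    return min(edlib.align(a, x, mode="NW")["editDistance"]
               for x in (b, util.revcomp(b)))
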