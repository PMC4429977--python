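import io

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# A curated bacterial record in the tab-separated flat dialect: wrapped FT
# descriptions, /FTId continuations, four single-site MOD_RES features of
# which two collide at position 12, CROSSLNK/UNSURE features to be ignored,
# and a 14-residue sequence split over whitespace blocks.  The ID/OC lines
# are synthetic wrappers (the excerpt circulates without them).
TABLE6_RECORD = """\
ID\tAMIS_AMISM\tReviewed;\t14 AA.
OC\tBacteria; Actinomycetota; synthetic lineage.
FT\tPEPTIDE\t1\t14\tAmythiamicin A/B.
FT\t\t\t\t/FTId = PRO_0000368029.
FT\tPEPTIDE\t1\t12\tAmythiamicin C/D.
FT\t\t\t\t/FTId = PRO_0000368030.
FT\tMOD_RES\t3\t3\tN4-methylasparagine.
FT\tMOD_RES\t12\t12\tCyclo[(prolylserin)-O-yl] cysteinate; in
FT\t\t\t\tform C.
FT\tMOD_RES\t12\t12\tCysteine methyl ester; in form D.
FT\tMOD_RES\t14\t14\tProline amide; in form A and form B.
FT\tCROSSLNK\t1\t11\tPyridine-2,5-dicarboxylic acid (Ser-Ser)
FT\t\t\t\t(with C-10).
FT\tCROSSLNK\t1\t10\tPyridine-2,5-dicarboxylic acid (Ser-Cys)
FT\t\t\t\t(with S-11).
FT\tCROSSLNK\t1\t2\tThiazole-4-carboxylic acid (Ser-Cys).
FT\tCROSSLNK\t3\t4\t5-methylthiazole-4-carboxylic acid (Asn-
FT\t\t\t\tCys).
FT\tCROSSLNK\t5\t6\tThiazole-4-carboxylic acid (Val-Cys).
FT\tCROSSLNK\t8\t9\tThiazole-4-carboxylic acid (Val-Cys).
FT\tCROSSLNK\t9\t10\tThiazole-4-carboxylic acid (Cys-Cys).
FT\tCROSSLNK\t11\t12\tThiazole-4-carboxylic acid (Ser-Cys).
FT\tCROSSLNK\t12\t13\tOxazoline-4-carboxylic acid (Cys-Ser); in
FT\t\t\t\tform A.
FT\tUNSURE\t4\t4\tC or T.
SQ\tSEQUENCE\t14 AA;\t1365 MW;\t3EB862761A777DC8 CRC64;
\tSCNCVCGVCC\t\t\tSCSP
//
"""

# Two short natural proteins: a phage tail-fiber fragment and a mussel
# adhesive-plaque protein.  Both reduce to a unique count of 6.
VG22_SEQ = "KAEEEVEKNKEEAEEEAEKKIAE"
PHI_SEQ = "AKAKRSPRKKKAAVKKSSKSKAKKPKSPKKKKAAKKPAKKAAKKK"


@pytest.fixture
def table6_stream():
    return io.StringIO(TABLE6_RECORD)


@pytest.fixture(scope="session")
def small_corpus():
    """A 2,000-protein annotated corpus with ground truth (seeded)."""
    from coiprot import CorpusConfig, generate_corpus

    config = CorpusConfig(m=2000, n_species=50)
    records, truth = generate_corpus(config, seed=7)
    return config, records, truth
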