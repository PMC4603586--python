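import pytest

import bzipfam as bz


@pytest.fixture(scope="session")
def rules():
    return bz.default_rule_table()


@pytest.fixture(scope="session")
def small_family():
    """A 40-protein synthetic family with planted truth, shared read-only."""
    return bz.generate_family(bz.default_spec(40, seed=11))


@pytest.fixture(scope="session")
def family_paths(small_family, tmp_path_factory):
    """The small family written to disk (FASTA/GFF3/Ct/truth)."""
    outdir = tmp_path_factory.mktemp("family")
    return bz.write_family(small_family, outdir)


def make_bzip_protein(
    pid="P1",
    pad="MSGYA",
    neg18="N",
    neg10="R",
    zipper="LAAVSTQ" * 3,
    tail="",
    basic_fill="F",  # F matches no hinge-keyed group rule
):
    """Hand-build a protein with one canonical N-x7-R/K-x9 anchor.

    The basic/hinge block is ``neg18`` + 7 fill + ``neg10`` + 9 fill,
    then the zipper starting at +1, then an optional tail.
    """
    basic = neg18 + basic_fill * 7 + neg10 + basic_fill * 9
    return bz.ProteinRecord(id=pid, sequence=pad + basic + zipper + tail)
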