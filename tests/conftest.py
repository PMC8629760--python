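import pytest

from tieraudit.io import GenotypeCall, Pedigree, PedigreeMember, SmallVariantRecord
from tieraudit.panels import PanelAssignment, bundled_registry
from tieraudit.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return bundled_registry()


@pytest.fixture(scope="session")
def assignment():
    return PanelAssignment("case", ("craniosynostosis", "dd_syndromes"))


@pytest.fixture
def trio():
    return Pedigree(
        "FAM1",
        (
            PedigreeMember("child", "dad", "mum", "female", "affected", is_proband=True),
            PedigreeMember("dad", sex="male", affected="unaffected"),
            PedigreeMember("mum", sex="female", affected="unaffected"),
        ),
    )


def make_record(ped, gene="TWIST1", chrom="chr7", pos=1_001_000, ref="C", alt="T",
                consequence="lof", pop_af=0.0, flags=(), **genotypes):
    """Build a small-variant record; genotypes default to reference."""
    ref_call = GenotypeCall(0, 30, 0)
    return SmallVariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=consequence,
        pop_af=pop_af, qual=99.0, flags=frozenset(flags),
        genotypes=tuple((sid, genotypes.get(sid, ref_call)) for sid in ped.sample_ids),
    )


HET = GenotypeCall(1, 30, 15)
HOM = GenotypeCall(2, 30, 30)
REF = GenotypeCall(0, 30, 0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact generated cohort shared across tests (30 families, all
    twelve archetypes planted once, light background)."""
    config = CohortConfig(
        n_families=30,
        trio_fraction=20 / 30,
        multiplex_count=3,
        background_variants_per_genome=10,
        seed=11,
    )
    return generate_cohort(config, tmp_path_factory.mktemp("cohort"))
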