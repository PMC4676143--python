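import pytest

from spfam.synth import FamilySpec, make_family, make_scaffolds, make_expression


@pytest.fixture(scope="session")
def full_family():
    """Seed-fixed synthetic family at the analysed genome's composition:
    221 genes = 120 SP + 101 SPH, 38 trypsins, 8 chymotrypsins, 13
    clip-bearing genes with 14 clip domains."""
    spec = FamilySpec(seed=11)
    records, manifest = make_family(spec)
    return records, manifest


@pytest.fixture(scope="session")
def full_layout(full_family):
    records, manifest = full_family
    models = make_scaffolds(manifest, records)
    return records, manifest, models


@pytest.fixture(scope="session")
def full_expression(full_family):
    records, manifest = full_family
    stage, tissue = make_expression(manifest)
    return manifest, stage, tissue


@pytest.fixture()
def small_family():
    spec = FamilySpec(
        n_sp=12, n_sph=8, n_trypsin=5, n_chymotrypsin=2,
        n_clip_sp=3, n_clip_sph=1, n_double_clip=1, seed=3,
    )
    return make_family(spec)
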