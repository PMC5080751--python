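import pytest

from polysd import (
    GenotypeCall,
    GenotypeMatrix,
    Marker,
    MarkerSpec,
    SDLocus,
    SexDeterminationModel,
    default_layout,
    simulate_family,
    zw_locus,
)


def build_matrix(markers, genotypes, depths=None):
    """Assemble a GenotypeMatrix from {individual: {marker_id: "A/C" | None}}."""
    individuals = list(genotypes)
    matrix = GenotypeMatrix(markers, individuals)
    for ind, calls in genotypes.items():
        for mid, token in calls.items():
            d = (depths or {}).get(ind, {}).get(mid, 0)
            if token is None:
                matrix.set_call(ind, mid, GenotypeCall(None, None, d))
            else:
                a, b = token.split("/")
                matrix.set_call(ind, mid, GenotypeCall(a, b, d))
    return matrix


@pytest.fixture
def two_marker_matrix():
    markers = [
        Marker("m1", scaffold="s1", position=100, alleles=("A", "C")),
        Marker("m2", scaffold="s1", position=900, alleles=("G", "T")),
    ]
    genotypes = {
        "ind1": {"m1": "A/C", "m2": "G/G"},
        "ind2": {"m1": "A/A", "m2": "G/T"},
        "ind3": {"m1": "C/C", "m2": "T/T"},
    }
    return build_matrix(markers, genotypes)


@pytest.fixture(scope="session")
def xy_family():
    """24-offspring cross with a paternal Y on LG1, full penetrance."""
    layout = default_layout(n_lgs=2, markers_per_lg=8)
    model = SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), 1.0)
    spec = MarkerSpec(ssr_fraction=1.0)
    return simulate_family(layout, model, 24, spec, seed=11)


@pytest.fixture(scope="session")
def zw_family():
    """24-offspring cross with a maternal W on LG2, full penetrance."""
    layout = default_layout(n_lgs=2, markers_per_lg=8)
    model = SexDeterminationModel((zw_locus("LG2", 15_000_000),), 1.0)
    spec = MarkerSpec(ssr_fraction=1.0)
    return simulate_family(layout, model, 24, spec, seed=12)
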