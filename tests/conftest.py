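import pytest

import bilineage as bl


@pytest.fixture(scope="session")
def tiny_design():
    """A desk-scale layout: 6 genes x 3 constructs x 3 wells, small plates."""
    return bl.ScreenDesign(
        n_genes=6,
        constructs_per_gene=(3, 3),
        replicates_per_construct=3,
        cells_per_well_mean=300,
        controls_per_plate=12,
        wells_per_plate=96,
        n_gating_control_wells_per_line=2,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_design):
    """One fixed tiny screen shared by read-only tests."""
    return bl.generate_screen(tiny_design, bl.EffectModel(),
                              bl.IntensityModel(), seed=7)
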