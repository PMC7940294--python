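import numpy as np
import pytest

from oribatida import (
    PlotRecord,
    SpecimenRecord,
    SpeciesTrait,
    build_community_matrix,
)


@pytest.fixture
def forest_plots():
    """Five ALB forest plots spanning the management gradient."""
    return [
        PlotRecord(
            plot_id=f"F{k}",
            region="ALB",
            habitat="forest",
            landuse={"Formi": v, "Iharv": v, "Inonat": v, "Idwcut": v},
        )
        for k, v in enumerate([0.0, 0.25, 0.5, 0.75, 1.0], start=1)
    ]


@pytest.fixture
def grassland_plots():
    return [
        PlotRecord(
            plot_id=f"G{k}",
            region="SCH",
            habitat="grassland",
            landuse={"LUI": v, "fertilization": 30 * v, "mowing": v, "grazing": 100 * v},
        )
        for k, v in enumerate([0.5, 1.5, 2.5], start=1)
    ]


@pytest.fixture
def toy_specimens():
    """Two species over two forest plots with known sexes and egg loads."""
    recs = []
    # species A: 3 individuals on F1 (subsamples 1, 1, 4), 1 on F2
    recs += [
        SpecimenRecord("F1", 1, "A", "female", gravid=True, egg_count=2),
        SpecimenRecord("F1", 1, "A", "female"),
        SpecimenRecord("F1", 4, "A", "male"),
        SpecimenRecord("F2", 2, "A", "female", gravid=True, egg_count=3),
    ]
    # species B: 2 individuals on F2
    recs += [
        SpecimenRecord("F2", 3, "B", "female"),
        SpecimenRecord("F2", 5, "B", "undetermined"),
    ]
    return recs


@pytest.fixture
def toy_matrix(toy_specimens, forest_plots):
    return build_community_matrix(toy_specimens, forest_plots)


@pytest.fixture
def toy_traits():
    return [
        SpeciesTrait("A", mode="sexual", body_size_um=300.0),
        SpeciesTrait("B", mode="parthenogenetic", body_size_um=500.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
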