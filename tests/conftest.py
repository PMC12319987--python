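import numpy as np
import pytest

from latnet import (
    Parcellation,
    SubjectParcellation,
    SurfaceMesh,
    icosphere_mesh,
)


@pytest.fixture
def triangle_mesh():
    """Single right triangle of area 0.5 in the z=0 plane."""
    return SurfaceMesh(
        "left",
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )


@pytest.fixture(scope="session")
def ico3_left():
    return icosphere_mesh(subdivisions=3, radius=100.0, hemisphere="left")


@pytest.fixture(scope="session")
def ico3_right():
    return icosphere_mesh(subdivisions=3, radius=100.0, hemisphere="right")


@pytest.fixture(scope="session")
def ico2_pair():
    return (
        icosphere_mesh(subdivisions=2, radius=100.0, hemisphere="left"),
        icosphere_mesh(subdivisions=2, radius=100.0, hemisphere="right"),
    )


def make_subject(labels_left, labels_right, label_table, subject_id="s1"):
    return SubjectParcellation(
        subject_id,
        Parcellation("left", np.asarray(labels_left), label_table),
        Parcellation("right", np.asarray(labels_right), label_table),
    )


@pytest.fixture
def toy_subject():
    """6 vertices per hemisphere, two networks plus unassigned."""
    table = {1: "net1", 2: "net2"}
    return make_subject([1, 1, 2, 2, 0, 0], [1, 2, 2, 2, 0, 1], table)
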