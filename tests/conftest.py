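import pytest

from hemavol import BlobSpec, make_blob, make_cube, make_pyramid


@pytest.fixture(scope="session")
def pyramid():
    """Benchmark quadrangular pyramid 30 x 30 x 20, analytic volume 6000."""
    return make_pyramid(30.0, 30.0, 20.0, subdivision=2)


@pytest.fixture(scope="session")
def cube():
    """Benchmark cube of edge 10, analytic volume 1000."""
    return make_cube(10.0, subdivision=4)


@pytest.fixture(scope="session")
def blob_regular():
    return make_blob(BlobSpec.for_class("regular", seed=3, subdivision_level=3))


@pytest.fixture(scope="session")
def blob_irregular():
    return make_blob(BlobSpec.for_class("irregular", seed=7, subdivision_level=3))


@pytest.fixture(scope="session")
def blob_lobular():
    return make_blob(BlobSpec.for_class("lobular", seed=11, subdivision_level=3))
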