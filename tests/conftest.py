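import numpy as np
import pytest

from migrascape.geo import BoundingBox, GeoPoint, build_lattice


@pytest.fixture(scope="session")
def square_bbox():
    return BoundingBox(GeoPoint(0.0, 2.0), GeoPoint(2.0, 0.0))


@pytest.fixture(scope="session")
def small_lattice(square_bbox):
    """~30-deme lattice on a 2x2 degree box near the equator."""
    return build_lattice(square_bbox, 30)


@pytest.fixture
def segment_file_factory(tmp_path):
    """Write hap-ibd style rows to a temp file and return its path."""

    def _write(rows, name="toy.ibd"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return path

    return _write


def make_rows(specs):
    """specs: iterable of (id1, id2, length_cM) -> full 8-column rows."""
    rows = []
    for i, (a, b, ln) in enumerate(specs):
        start = 1000 + i * 10
        rows.append((a, 1, b, 1, "1", start, start + int(ln * 1e6), ln))
    return rows
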