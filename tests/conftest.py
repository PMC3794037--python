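import pytest

from streetsurvey import Extent, RoadSegment


@pytest.fixture
def unit_extent() -> Extent:
    return Extent(0.0, 0.0, 10.0, 10.0)


def hroad(y: float, x0: float, x1: float, rid: str = "r0", covered: bool = False) -> RoadSegment:
    """Horizontal road segment at height y."""
    return RoadSegment(id=rid, vertices=[(x0, y), (x1, y)], covered=covered)
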