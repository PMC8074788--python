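import pytest

from scutemark.marker_db import (
    BUNDLED_TEMPLATES,
    Marker,
    MarkerDatabase,
    bundled_database,
)
from scutemark.synthetic_s1 import enriched_database


@pytest.fixture(scope="session")
def bundled_db():
    return bundled_database()


@pytest.fixture(scope="session")
def full_db():
    """Bundled database enriched with the full-scale synthetic supplement."""
    return enriched_database()


@pytest.fixture()
def toy_db():
    """Three-species toy database with hand-placed repertoires."""
    sp1, sp2, sp3 = ("Chelonia mydas", "Caretta caretta", "Eretmochelys imbricata")
    markers = [
        Marker("E4b-t1", "E4b", "YGGAAGYR", frozenset({sp1})),
        Marker("E4b-t2", "E4b", "YGGSSGYR", frozenset({sp1, sp2})),
        Marker("E4b-t3", "E4b", "YGGLLGYR", frozenset({sp2, sp3})),
        Marker("E2c-t1", "E2c", "LGGFGGLAR", frozenset({sp3})),
        Marker("E2c-t2", "E2c", "LGGFGGLSR", frozenset({sp1, sp2, sp3})),
    ]
    return MarkerDatabase(templates=list(BUNDLED_TEMPLATES), markers=markers,
                          species=[sp1, sp2, sp3],
                          genus_map={sp1: "Chelonia", sp2: "Caretta",
                                     sp3: "Eretmochelys"})
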